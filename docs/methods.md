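# Methods

`nanolibkit` implements a desk-scale pipeline for building synthetic
nanobody (VHH) libraries from a germline-conditional sequence generator:
repertoire curation against germline V-gene references, a small
autoregressive language model fine-tuned with low-rank adapters under a
germline instruction tag, IMGT numbering and CDR delimitation by anchor
transfer, post-translational-modification (PTM) liability scanning,
positional amino-acid frequency statistics, and framework-grafted
library synthesis. This note records the models, the defaults and why
they were chosen, and what the synthetic-data regime does and does not
demonstrate.

## Germline references and fixtures

Two germline V-gene references are bundled, emulating the alpaca
IGHV3-3\*01 and IGHV3S53\*01 entries of the IMGT scheme. Each reference
is the V-region prefix (IMGT positions 1–104, ending at the second
conserved cysteine) of the corresponding full library framework, which
is also bundled. The IMGT maps were assigned by hand following the
standard IGHV3 gapping: FR1 lacks position 10; an 8-residue CDR1
occupies 27–30/35–38; an 8-residue CDR2 occupies 56–59/62–65 (7-residue:
56–59/63–65); FR3 lacks position 73. Both maps place cysteines at IMGT
23 and 104 and the invariant tryptophan at 41, and these constraints are
validated at load time. The two references differ at 22% of shared IMGT
positions, which makes germline assignment identifiable: a sequence
derived from one reference at realistic mutation rates is ~95% identical
to its own germline and ~78% identical to the other.

## Curation

Assignment aligns the query to every reference with a global pairwise
alignment (BLOSUM62, gap open 11, extend 1, free end gaps) and picks the
highest framework identity; ties break by reference name. Identity is
computed over alignment columns where the *reference* has a residue:
the CDR3/FR4 overhang of a full-length domain against a V gene that ends
at position 104 would otherwise count as a block of gap mismatches.
End gaps are unpenalised for the same reason. Curation drops exact
duplicate sequences, lengths outside 90–160 aa (VHH domains cluster at
110–130 aa; the bounds are configurable), and sequences not strictly
above 85% identity to their best reference, then splits 80/20 into
train/test with a single integer seed. The identity threshold applies to
the best-matching germline, and curation is idempotent: re-curating a
curated split rejects nothing.

## IMGT numbering by anchor transfer

Full profile-HMM numbering is unnecessary inside the curated regime,
where every sequence is >85% identical to a known reference. Instead the
query is aligned to its reference and every reference-aligned residue
inherits the reference's IMGT number; insertions take insertion codes on
the preceding number. The tail past position 104 is split by
right-anchoring FR4 (118–128) on the J-segment motif `WGQG`; the loop in
between is numbered by the IMGT junction convention for CDR3 (105–117,
apex gaps for short loops, paired 111.x/112.x insertion codes for long
ones). Sequences below 50% identity to the reference are refused as
unnumberable rather than numbered badly. Regions follow the IMGT
delimitation (CDR1 27–38, CDR2 56–65, CDR3 105–117) and always tile the
sequence; a missing flanking anchor (e.g. a domain truncated before
position 105) is an error naming the gap.

## Generator

The generator is a deliberately small LLaMA-style decoder: pre-RMSNorm,
multi-head causal self-attention, SwiGLU feed-forward, learned absolute
position embeddings, written in numpy with hand-derived gradients so the
freeze semantics are explicit and auditable. Defaults: d_model 128,
4 layers, 4 heads, d_ff 256, context 160, vocabulary of 20 amino acids
plus begin/end/pad, a generic tag, and one tag token per germline
(~684k base parameters).

Fine-tuning follows low-rank adaptation: each of the seven projection
matrices per layer (wq, wk, wv, wo, wgate, wup, wdown) keeps its frozen
base value W0 and learns an additive update A·B with A ∈ R^{d×r},
B ∈ R^{r×k}, r ≪ d,k. B is zero-initialised, so the adapted model is
bit-identical to its base before the first update — asserted exactly in
the tests. The base is hashed before and after adapter training and the
digests must match (the freeze contract). The default rank r = 5 puts
the trainable fraction at 6.0% of all parameters, the regime low-rank
fine-tuning is meant to occupy; no α/r rescaling is applied (scale 1.0,
configurable). Rank, learning rates and epoch counts are this package's
choices: a 7B-parameter model fine-tuned from a pretrained protein
language model does not pin down hyper-parameters for a 700k-parameter
one.

Because the toy base starts from random weights rather than from a
pretrained protein model, training has two stages: `pretrain` fits the
whole base on the pooled sequences with the tag slot filled by a generic
token (3 epochs, Adam lr 1e-3), then `train` freezes the base and fits
only the adapters on germline-tagged data (6 epochs, Adam lr 1e-2,
batch 32). Conditioning is a single categorical tag token rather than a
natural-language instruction: the tag carries the entire conditioning
signal, and the phrasing around it adds nothing at this scale.

Sampling prefixes `[tag][begin]` and draws tokens at temperature 1.0
until the end token; only amino-acid and end tokens are reachable.
Samples failing alphabet validation or (when references are supplied)
IMGT numberability are dropped and resampled; duplicates are dropped so
the output is a set of unique sequences; an attempt cap of 10n returns a
partial result with a warning rather than looping forever.

A PSSM baseline sampler (`fit_pssm`/`sample_pssm`) is included as the
purely statistical reference point: per-region, per-length column
frequencies with additive smoothing 0.01, frameworks copied from the
fixture framework.

## Liability scanning

The motif table is data (TSV), not code. Default high-risk rules:
N-glycosylation sequon `N[^P][ST]`, deamidation NG/NS/NT, isomerization
DG/DS/DT, hydrolysis DP, and any cysteine outside the conserved IMGT
23/104 pair (counted once per residue); medium-risk: methionine and
tryptophan oxidation, weak deamidation NN/NA. These are standard
antibody developability conventions; alternative counting conventions
are reproduced by swapping the table. The scan is a deterministic
left-to-right pass reporting all overlapping matches. Unpaired-cysteine
detection needs the numbering (to locate 23/104); without it, cysteines
are left unclassified rather than guessed. Under this table the two
bundled frameworks carry 4 and 3 high-risk sites respectively — both
within the "fewer than 10" regime that motivated their selection.

## Library statistics and synthesis

Positional frequency matrices are raw per-column frequencies (no
smoothing — logos display raw statistics), stratified by germline,
region and CDR3 loop length. The default CDR3 ranges retained for
statistics are 15–19 (IGHV3-3\*01) and 12–16 (IGHV3S53\*01), the
most-populated strata; logo exports default to lengths 17 and 14
respectively. Library members graft independently sampled CDRs into the
fixed framework: CDR1 and CDR2 from their PFMs, CDR3 from a length
stratum drawn by weight (empirical stratum support by default, uniform
by flag), each column sampled independently. Per-site frequencies are
the entire statistical model; pairwise couplings are deliberately out of
scope. Members are deduplicated, always pass validation, and retain the
conserved cysteine pair by construction since the framework supplies
FR1/FR3.

## Synthetic repertoires

`simdata` emulates an experimental repertoire: each sequence derives
from the germline's framework by per-column substitution (framework
rate 0.03 — typical framework divergence inside the >85% curated
regime; CDR1/2 rate 0.10) with the CDR3 resampled wholesale at a drawn
length from a fixed per-germline residue profile. Substitutions are
uniform over the 19 alternatives — the simplest null for recovery tests
(a substitution-matrix-biased sampler can be plugged in). Anchor
protection keeps IMGT 23/104, the region-flanking anchors and the FR4
`WGQG` motif untouched. A truth table (germline, CDR strings, mutation
positions) accompanies every repertoire, so numbering, assignment and
PFM estimation are all tested by parameter recovery.

What this regime does not show: real repertoires have
substitution-biased, hotspot-clustered somatic mutation, indels in
loops, allelic variation and sequencing noise, and real germline
assignment must discriminate among dozens of closely related V genes,
not two references 22% apart. Passing here demonstrates the machinery
is correct in the regime the pipeline curates for, not that accuracy
numbers transfer to noisy experimental data.

## Reference experiment and problem sizes

The headline reproduction (`experiments.conditioning_experiment`)
simulates 500 sequences per germline (framework rate 0.03, anchors
protected), pretrains 3 epochs, trains adapters 6 epochs, generates
1,000 sequences per conditioning tag and measures generation accuracy by
best-identity assignment. At these sizes the run takes a few minutes on
one CPU core and reaches ≥99% accuracy for both tags with seed 1.

## Numerical and degenerate-input choices

* float32 throughout the network; RMSNorm ε = 1e-6; attention masked
  with −1e9 additive logits; softmax max-subtracted.
* Alignment ties break by Biopython's canonical enumeration order
  (matches preferred over gaps), then by reference name.
* PFM columns are validated to sum to 1 within 1e-9; information content
  is log2(20) − H(column), in [0, log2 20].
* Empty sequence: validation reports a violation at position 0;
  alignment raises.
* All-rejected curation raises naming the dominant rejection reason;
  an exhausted diversity or sampling attempt cap returns a partial
  result with a warning rather than failing.
* Every random path (simulation, splits, initialisation, training order,
  sampling) flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

* Two germlines only; the numbering is anchor transfer, valid near a
  known reference, not a general-purpose numberer.
* No structure-based evaluation (pLDDT/TM-score) — sequence-level checks
  only; the cysteine check is a sequence-level necessary condition for
  the conserved disulfide, not evidence of bond formation.
* No humanization scoring; no codon-level oligo design; CDR columns are
  modelled independently.
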