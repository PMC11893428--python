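"""Germline assignment and dataset curation.

Sequences are assigned to the germline V-gene reference they are most
similar to under a global pairwise alignment, and a repertoire is curated
by dropping duplicates, unreasonable lengths, and sequences below an
identity floor against their best-matching germline, followed by a seeded
80/20 train/test split.

"Identity" here is framework identity: the fraction of reference residues
matched by the query across alignment columns where the reference has a
residue. Columns where the reference is gapped (e.g. the long CDR3
insertion of a full-length query against a V gene ending at IMGT 104) do
not enter the denominator; reference positions deleted in the query count
as mismatches.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

#: Default identity floor: strictly more than 85% framework consistency.
MIN_IDENTITY = 0.85
#: Default length bounds for a plausible VHH domain (aa).
LENGTH_BOUNDS = (90, 160)
#: Default train fraction of the 80/20 split.
TRAIN_FRACTION = 0.80


@dataclass
class GermlineReference:
    """A germline V-gene protein sequence with its IMGT position map.

    ``imgt_map`` pairs every 0-based residue index with its IMGT position
    number, strictly increasing; the conserved cysteines sit at IMGT 23
    and 104 when those positions are covered.
    """

    name: str
    seq: str
    imgt_map: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        idxs = [i for i, _ in self.imgt_map]
        if idxs != list(range(len(self.seq))):
            raise ValueError(
                f"{self.name}: imgt_map must cover every residue exactly once"
            )
        nums = [g for _, g in self.imgt_map]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"{self.name}: IMGT numbers must be strictly increasing")
        pos = self.position_lookup()
        for cys in (23, 104):
            if cys in pos and self.seq[pos[cys]] != "C":
                raise ValueError(
                    f"{self.name}: IMGT {cys} is {self.seq[pos[cys]]!r}, expected C"
                )

    def position_lookup(self) -> Dict[int, int]:
        """Mapping IMGT position -> residue index."""
        return {g: i for i, g in self.imgt_map}


@dataclass
class GermlineAssignment:
    query_id: str
    best_germline: str
    identity: float
    runner_up_identity: float


@dataclass
class PairwiseAlignment:
    """A global alignment of query against reference as two gapped strings."""

    query: str
    reference: str
    aligned_query: str
    aligned_reference: str
    score: float


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Global protein aligner with free end gaps.

    End gaps are unpenalised so that a full-length domain can be scored
    against a V-gene reference that stops at IMGT 104 without the CDR3/FR4
    overhang distorting the framework alignment.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def align_global(
    a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> PairwiseAlignment:
    """Globally align query ``a`` against reference ``b``.

    Deterministic: of all optimal alignments the first in Biopython's
    canonical enumeration order is returned, which prefers matches over
    gaps at equal score.
    """
    if not a or not b:
        raise ValueError("align_global: sequences must be non-empty")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(a, b)[0]
    qa, ra = str(aln[0]), str(aln[1])
    return PairwiseAlignment(
        query=a, reference=b, aligned_query=qa, aligned_reference=ra, score=aln.score
    )


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Fraction of reference residues matched by the query.

    Counted over alignment columns where the reference is not gapped;
    gaps in the query at such columns count as mismatches.
    """
    matches = 0
    ref_cols = 0
    for qc, rc in zip(alignment.aligned_query, alignment.aligned_reference):
        if rc == "-":
            continue
        ref_cols += 1
        if qc == rc:
            matches += 1
    return matches / ref_cols if ref_cols else 0.0


def assign_germline(
    rec: SequenceRecord, refs: Sequence[GermlineReference]
) -> GermlineAssignment:
    """Assign ``rec`` to its highest-identity germline reference.

    Ties break deterministically by reference name order.
    """
    if not refs:
        raise ValueError("assign_germline: empty reference list")
    scored = []
    for ref in refs:
        ident = percent_identity(align_global(rec.seq, ref.seq))
        scored.append((-ident, ref.name))
    scored.sort()
    best_ident = -scored[0][0]
    runner_up = -scored[1][0] if len(scored) > 1 else 0.0
    return GermlineAssignment(
        query_id=rec.id,
        best_germline=scored[0][1],
        identity=best_ident,
        runner_up_identity=runner_up,
    )


@dataclass
class CuratedDataset:
    """Outcome of :func:`curate_dataset`.

    ``rejected`` records every dropped input as ``(id, reason)`` with
    reason in {duplicate, length, identity}; retained records carry their
    assigned germline label and are split ~80/20 into train/test.
    """

    train: List[SequenceRecord]
    test: List[SequenceRecord]
    rejected: List[Tuple[str, str]]
    params: Dict[str, object] = field(default_factory=dict)


def curate_dataset(
    records: Sequence[SequenceRecord],
    refs: Sequence[GermlineReference],
    min_identity: float = MIN_IDENTITY,
    length_bounds: Tuple[int, int] = LENGTH_BOUNDS,
    split: float = TRAIN_FRACTION,
    seed: int = 0,
) -> CuratedDataset:
    """Curate a repertoire: dedup, length filter, identity filter, split.

    Filters apply in order — exact-sequence duplicates first (first
    occurrence kept), then length bounds, then strict ``identity >
    min_identity`` against the best-matching germline. Retained records
    are relabelled with their assigned germline and split into train/test
    reproducibly from ``seed``; rejected records appear in neither split.
    """
    rejected: List[Tuple[str, str]] = []
    seen: set = set()
    kept: List[SequenceRecord] = []
    lo, hi = length_bounds
    for rec in records:
        if rec.seq in seen:
            rejected.append((rec.id, "duplicate"))
            continue
        seen.add(rec.seq)
        if not (lo <= len(rec.seq) <= hi):
            rejected.append((rec.id, "length"))
            continue
        assignment = assign_germline(rec, refs)
        if not assignment.identity > min_identity:
            rejected.append((rec.id, "identity"))
            continue
        kept.append(
            SequenceRecord(
                id=rec.id, seq=rec.seq, germline_label=assignment.best_germline
            )
        )
    if records and not kept:
        counts: Dict[str, int] = {}
        for _, reason in rejected:
            counts[reason] = counts.get(reason, 0) + 1
        dominant = max(counts, key=lambda r: counts[r])
        raise ValueError(
            f"curate_dataset: all {len(records)} records rejected "
            f"(dominant reason: {dominant}, {counts[dominant]} records)"
        )
    order = list(range(len(kept)))
    random.Random(seed).shuffle(order)
    n_train = round(len(kept) * split)
    train = [kept[i] for i in sorted(order[:n_train])]
    test = [kept[i] for i in sorted(order[n_train:])]
    return CuratedDataset(
        train=train,
        test=test,
        rejected=rejected,
        params={
            "min_identity": min_identity,
            "length_bounds": length_bounds,
            "split": split,
            "seed": seed,
        },
    )
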