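"""Synthetic germline-derived repertoires.

Emulates an experimental VHH repertoire at desk scale: each sequence is
derived from a germline's fixture framework by per-column substitution
(framework columns at a low rate, CDR1/CDR2 columns at a higher rate)
with the CDR3 loop resampled wholesale at a drawn length from a fixed
per-germline residue profile. Anchor protection keeps the conserved
IMGT 23/104 cysteines, the region-flanking anchors and the FR4 ``WGQG``
motif untouched so that every simulated sequence remains numberable and
its regions recoverable.

A truth table records, per sequence, the germline, the true CDR strings
and every mutated position, so downstream modules can be tested by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fixtures import GERMLINES, load_frameworks, load_references
from .numbering import (
    CONSERVED_CYS,
    RegionAnnotation,
    extract_regions,
    number_sequence,
)
from .seqio import AMINO_ACIDS, SequenceRecord

#: Default CDR3 length ranges per germline (inclusive), matching the
#: length strata used for library statistics.
DEFAULT_CDR3_RANGES: Dict[str, Tuple[int, int]] = {
    "IGHV3-3*01": (15, 19),
    "IGHV3S53*01": (12, 16),
}

# Fixed per-germline CDR3 residue profiles (no position dependence).
# Cysteine is excluded so simulated loops never add unpaired cysteines;
# the two germlines get distinct profiles so loop composition carries a
# weak germline signal, as in real repertoires.
_CDR3_PROFILES: Dict[str, Dict[str, float]] = {
    "IGHV3-3*01": {
        "G": 0.14, "R": 0.11, "S": 0.10, "Y": 0.10, "D": 0.09, "A": 0.08,
        "T": 0.07, "V": 0.06, "L": 0.05, "P": 0.05, "E": 0.04, "N": 0.03,
        "W": 0.02, "F": 0.02, "K": 0.01, "I": 0.01, "Q": 0.01, "H": 0.005,
        "M": 0.005,
    },
    "IGHV3S53*01": {
        "S": 0.13, "G": 0.11, "V": 0.10, "A": 0.09, "L": 0.08, "N": 0.08,
        "R": 0.07, "P": 0.06, "Y": 0.06, "K": 0.05, "T": 0.05, "D": 0.04,
        "E": 0.03, "F": 0.02, "I": 0.01, "Q": 0.01, "W": 0.005, "H": 0.005,
        "M": 0.0,
    },
}


def seed_cdr3_profile(germline: str) -> Dict[str, float]:
    """The fixed CDR3 residue profile a repertoire draws its loops from."""
    prof = dict(_CDR3_PROFILES[germline])
    total = sum(prof.values())
    return {aa: p / total for aa, p in prof.items()}


@dataclass
class RepertoireConfig:
    germline: str
    n: int
    framework_mutation_rate: float = 0.03
    cdr_mutation_rate: float = 0.10
    cdr3_length_distribution: Optional[Dict[int, float]] = None
    anchor_protection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.framework_mutation_rate <= 1:
            raise ValueError("framework_mutation_rate outside [0,1]")
        if not 0 <= self.cdr_mutation_rate <= 1:
            raise ValueError("cdr_mutation_rate outside [0,1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.cdr3_length_distribution is None:
            lo, hi = DEFAULT_CDR3_RANGES[self.germline]
            k = hi - lo + 1
            self.cdr3_length_distribution = {L: 1.0 / k for L in range(lo, hi + 1)}
        total = sum(self.cdr3_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cdr3_length_distribution must sum to 1")


@dataclass
class TruthRecord:
    id: str
    germline: str
    cdr1: str
    cdr2: str
    cdr3: str
    mutated_positions: List[int] = field(default_factory=list)


_FRAMEWORK_ANNOTATIONS: Dict[str, RegionAnnotation] = {}


def framework_annotation(germline: str) -> RegionAnnotation:
    """Region annotation of a germline's fixture framework (cached)."""
    if germline not in _FRAMEWORK_ANNOTATIONS:
        fw = load_frameworks()[germline]
        ref = next(r for r in load_references() if r.name == germline)
        _FRAMEWORK_ANNOTATIONS[germline] = extract_regions(
            number_sequence(fw, ref)
        )
    return _FRAMEWORK_ANNOTATIONS[germline]


def _protected_indices(germline: str) -> set:
    """Residue indices never mutated under anchor protection."""
    fw = load_frameworks()[germline]
    ref = next(r for r in load_references() if r.name == germline)
    numbering = number_sequence(fw, ref)
    lookup = numbering.label_lookup()
    protected = set()
    for pos in CONSERVED_CYS + (26, 39, 55, 66, 118, 119, 120, 121):
        idx = lookup.get((pos, 0))
        if idx is not None:
            protected.add(idx)
    return protected


def _uniform_substitution(rng: np.random.Generator, original: str) -> str:
    alternatives = [aa for aa in AMINO_ACIDS if aa != original]
    return alternatives[rng.integers(len(alternatives))]


def simulate_repertoire(
    config: RepertoireConfig,
    substitution_sampler: Callable[[np.random.Generator, str], str] = _uniform_substitution,
) -> Tuple[List[SequenceRecord], List[TruthRecord]]:
    """Draw a synthetic repertoire from a germline's fixture framework.

    Returns ``(records, truth)`` with one truth row per record.
    Reproducible from ``config.seed``; substitutions default to uniform
    over the 19 alternative residues (a substitution-matrix-biased
    sampler can be passed instead).
    """
    if config.germline not in GERMLINES:
        raise ValueError(f"unknown germline {config.germline!r}")
    rng = np.random.default_rng(config.seed)
    ann = framework_annotation(config.germline)
    protected = _protected_indices(config.germline) if config.anchor_protection else set()
    profile = seed_cdr3_profile(config.germline)
    prof_letters = [aa for aa in AMINO_ACIDS if profile.get(aa, 0.0) > 0]
    prof_p = np.array([profile[aa] for aa in prof_letters])
    prof_p = prof_p / prof_p.sum()
    lengths = sorted(config.cdr3_length_distribution)
    length_p = np.array([config.cdr3_length_distribution[L] for L in lengths])

    rate_of_region = {
        "FR1": config.framework_mutation_rate,
        "FR2": config.framework_mutation_rate,
        "FR3": config.framework_mutation_rate,
        "FR4": config.framework_mutation_rate,
        "CDR1": config.cdr_mutation_rate,
        "CDR2": config.cdr_mutation_rate,
    }
    tag = config.germline.replace("*", "x")
    records: List[SequenceRecord] = []
    truth: List[TruthRecord] = []
    for i in range(config.n):
        cdr3_len = int(rng.choice(lengths, p=length_p))
        cdr3 = "".join(
            prof_letters[j] for j in rng.choice(len(prof_letters), size=cdr3_len, p=prof_p)
        )
        out: List[str] = []
        mutated: List[int] = []
        pos = 0
        regions: Dict[str, str] = {}
        for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"):
            if name == "CDR3":
                regions[name] = cdr3
                out.append(cdr3)
                pos += cdr3_len
                continue
            s, e = ann.spans[name]
            template = ann.seq[s:e]
            rate = rate_of_region[name]
            built = []
            for k, aa in enumerate(template):
                src_idx = s + k
                if src_idx not in protected and rng.random() < rate:
                    new = substitution_sampler(rng, aa)
                    built.append(new)
                    mutated.append(pos + k)
                else:
                    built.append(aa)
            regions[name] = "".join(built)
            out.append(regions[name])
            pos += len(template)
        rid = f"{tag}_sim{i:05d}"
        records.append(
            SequenceRecord(id=rid, seq="".join(out), germline_label=config.germline)
        )
        truth.append(
            TruthRecord(
                id=rid,
                germline=config.germline,
                cdr1=regions["CDR1"],
                cdr2=regions["CDR2"],
                cdr3=regions["CDR3"],
                mutated_positions=mutated,
            )
        )
    return records, truth


def plant_motif(rec: SequenceRecord, motif: str, position: int) -> SequenceRecord:
    """Return a copy of ``rec`` with ``motif`` written in at ``position``."""
    if position < 0 or position + len(motif) > len(rec.seq):
        raise ValueError(
            f"plant_motif: motif of length {len(motif)} does not fit at "
            f"{position} in a {len(rec.seq)}-residue sequence"
        )
    seq = rec.seq[:position] + motif + rec.seq[position + len(motif):]
    return SequenceRecord(id=rec.id, seq=seq, germline_label=rec.germline_label)


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    """TSV export: id, germline, cdr1, cdr2, cdr3, mutated_positions."""
    with open(path, "w") as fh:
        fh.write("id\tgermline\tcdr1\tcdr2\tcdr3\tmutated_positions\n")
        for t in truth:
            muts = ",".join(str(p) for p in t.mutated_positions)
            fh.write(f"{t.id}\t{t.germline}\t{t.cdr1}\t{t.cdr2}\t{t.cdr3}\t{muts}\n")
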