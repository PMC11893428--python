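"""Library statistics and framework-grafted synthesis.

From a set of annotated sequences the per-germline, per-CDR, per-length
positional amino-acid frequencies are computed (the numbers a sequence
logo displays), CDR3s are stratified by loop length, and a synthetic
library is built by grafting independently sampled CDRs into a fixed
framework. Frequencies here are raw (unsmoothed) statistics: the logo of
a column containing a single residue is a point mass.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .germline import GermlineReference, assign_germline
from .numbering import RegionAnnotation
from .seqio import AMINO_ACIDS, SequenceRecord, validate_sequence

#: CDR3 length ranges selected for library statistics, per germline.
LIBRARY_CDR3_RANGES: Dict[str, Tuple[int, int]] = {
    "IGHV3-3*01": (15, 19),
    "IGHV3S53*01": (12, 16),
}
#: CDR3 length stratum shown first in logo exports, per germline.
LOGO_DEFAULT_CDR3_LENGTH: Dict[str, int] = {
    "IGHV3-3*01": 17,
    "IGHV3S53*01": 14,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class PositionFrequencyMatrix:
    """Raw per-column residue frequencies for one CDR length stratum.

    ``matrix`` has shape (length_stratum, 20), columns over the amino
    acids in alphabetical order; every row sums to 1.
    """

    germline: str
    region: str
    length_stratum: int
    matrix: np.ndarray
    support: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.length_stratum, 20):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({self.length_stratum}, 20)"
            )
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM columns must each sum to 1")

    def information_content(self) -> np.ndarray:
        """Per-column information content: log2(20) minus Shannon entropy."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return math.log2(20) + plogp.sum(axis=1)


def compute_pfm(
    annotations: Sequence[RegionAnnotation],
    germline: str,
    region: str,
    length_stratum: int,
) -> PositionFrequencyMatrix:
    """Raw positional frequencies of one CDR at one loop length."""
    attr = region.lower()
    strings = [getattr(a, attr) for a in annotations if len(getattr(a, attr)) == length_stratum]
    if not strings:
        raise ValueError(
            f"empty stratum: germline={germline} region={region} "
            f"length={length_stratum}"
        )
    counts = np.zeros((length_stratum, 20))
    for s in strings:
        for j, aa in enumerate(s):
            counts[j, _AA_INDEX[aa]] += 1
    return PositionFrequencyMatrix(
        germline=germline,
        region=region,
        length_stratum=length_stratum,
        matrix=counts / len(strings),
        support=len(strings),
    )


def stratify_cdr3(
    annotations: Sequence[RegionAnnotation],
    germline: str,
    length_range: Optional[Tuple[int, int]] = None,
) -> Dict[int, List[RegionAnnotation]]:
    """Group annotations by CDR3 length, keeping only lengths in range.

    The default range is the germline's library statistics range
    (15-19 for IGHV3-3*01, 12-16 for IGHV3S53*01).
    """
    if length_range is None:
        length_range = LIBRARY_CDR3_RANGES[germline]
    lo, hi = length_range
    strata: Dict[int, List[RegionAnnotation]] = {}
    for ann in annotations:
        L = len(ann.cdr3)
        if lo <= L <= hi:
            strata.setdefault(L, []).append(ann)
    return dict(sorted(strata.items()))


def export_logo_matrix(pfm: PositionFrequencyMatrix, path) -> None:
    """Write a logo-ready TSV: one row per column, 20 frequency fields in
    alphabetical residue order, plus the column information content."""
    ic = pfm.information_content()
    with open(Path(path), "w") as fh:
        header = ["column"] + list(AMINO_ACIDS) + ["information_content"]
        fh.write("\t".join(header) + "\n")
        for j in range(pfm.length_stratum):
            row = [str(j)] + [f"{v:.6f}" for v in pfm.matrix[j]] + [f"{ic[j]:.6f}"]
            fh.write("\t".join(row) + "\n")


def read_logo_matrix(path) -> np.ndarray:
    """Read back a logo TSV into an (L, 20) frequency array."""
    rows = []
    with open(Path(path)) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append([float(row[aa]) for aa in AMINO_ACIDS])
    return np.array(rows)


@dataclass
class LibraryDesign:
    """A framework with CDR slots plus the PFMs to fill them from.

    ``cdr3_pfms`` may hold several length strata; ``cdr3_weights`` gives
    the probability of drawing each stratum and must sum to 1.
    """

    germline: str
    framework: RegionAnnotation
    cdr1_pfm: PositionFrequencyMatrix
    cdr2_pfm: PositionFrequencyMatrix
    cdr3_pfms: List[PositionFrequencyMatrix]
    cdr3_weights: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cdr3_pfms:
            raise ValueError("LibraryDesign needs at least one CDR3 stratum")
        if not self.cdr3_weights:
            total = sum(p.support for p in self.cdr3_pfms)
            self.cdr3_weights = [p.support / total for p in self.cdr3_pfms]
        if len(self.cdr3_weights) != len(self.cdr3_pfms):
            raise ValueError("one weight per CDR3 stratum required")
        if abs(sum(self.cdr3_weights) - 1.0) > 1e-9:
            raise ValueError("cdr3_weights must sum to 1")


def design_from_annotations(
    germline: str,
    framework: RegionAnnotation,
    annotations: Sequence[RegionAnnotation],
    length_range: Optional[Tuple[int, int]] = None,
    uniform_weights: bool = False,
) -> LibraryDesign:
    """Build a LibraryDesign from annotated sequences.

    CDR1/CDR2 statistics use the framework's own loop lengths; CDR3 is
    stratified over ``length_range`` with weights proportional to
    stratum support (or uniform when requested).
    """
    strata = stratify_cdr3(annotations, germline, length_range)
    if not strata:
        raise ValueError(f"no CDR3 strata in range for {germline}")
    cdr3_pfms = [compute_pfm(anns, germline, "CDR3", L) for L, anns in strata.items()]
    weights: List[float] = []
    if uniform_weights:
        weights = [1.0 / len(cdr3_pfms)] * len(cdr3_pfms)
    return LibraryDesign(
        germline=germline,
        framework=framework,
        cdr1_pfm=compute_pfm(annotations, germline, "CDR1", len(framework.cdr1)),
        cdr2_pfm=compute_pfm(annotations, germline, "CDR2", len(framework.cdr2)),
        cdr3_pfms=cdr3_pfms,
        cdr3_weights=weights,
    )


def _sample_from_pfm(
    pfm: PositionFrequencyMatrix, rng: np.random.Generator
) -> str:
    cum = np.cumsum(pfm.matrix, axis=1)
    u = rng.random(pfm.length_stratum)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


def synthesize_library(
    design: LibraryDesign, n: int, seed: int = 0, attempt_factor: int = 20
) -> List[SequenceRecord]:
    """Graft independently sampled CDRs into the design framework.

    Each member draws CDR1 and CDR2 from their PFMs and CDR3 from a
    weight-chosen length stratum, column by column and independently
    across columns (per-site frequencies are the entire statistical
    model, as in logo-based library construction). Duplicates are
    dropped; if the attainable diversity is exhausted a partial library
    is returned with a warning.
    """
    rng = np.random.default_rng(seed)
    fw = design.framework
    fr = {name: fw.region_seq(name) for name in ("FR1", "FR2", "FR3", "FR4")}
    weights = np.array(design.cdr3_weights)
    out: List[SequenceRecord] = []
    seen: set = set()
    attempts = 0
    cap = max(attempt_factor * n, 1000)
    while len(out) < n and attempts < cap:
        attempts += 1
        stratum = design.cdr3_pfms[
            int(rng.choice(len(design.cdr3_pfms), p=weights))
        ]
        seq = (
            fr["FR1"]
            + _sample_from_pfm(design.cdr1_pfm, rng)
            + fr["FR2"]
            + _sample_from_pfm(design.cdr2_pfm, rng)
            + fr["FR3"]
            + _sample_from_pfm(stratum, rng)
            + fr["FR4"]
        )
        if seq in seen:
            continue
        assert validate_sequence(seq).ok
        seen.add(seq)
        out.append(
            SequenceRecord(
                id=f"lib_{design.germline.replace('*', 'x')}_{len(out):06d}",
                seq=seq,
                germline_label=design.germline,
            )
        )
    if len(out) < n:
        warnings.warn(
            f"synthesize_library: diversity exhausted, returning {len(out)}/{n}"
        )
    return out


def germline_accuracy(
    generated: Sequence[SequenceRecord],
    requested: str,
    refs: Sequence[GermlineReference],
) -> float:
    """Fraction of sequences assigned back to the requested germline."""
    if not generated:
        raise ValueError("germline_accuracy: empty sequence list")
    hits = sum(
        1
        for rec in generated
        if assign_germline(rec, refs).best_germline == requested
    )
    return hits / len(generated)
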