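"""Post-translational-modification liability scanning.

Sequence motifs prone to chemical modification are a standard
developability concern for antibody libraries: asparagine deamidation
(NG/NS/NT), aspartate isomerization (DG/DS/DT), N-linked glycosylation
sequons (N-X-S/T, X != P), Asp-Pro hydrolysis, methionine/tryptophan
oxidation, and cysteines outside the conserved IMGT 23/104 disulfide
pair. The motif table is data, not code (TSV: motif_regex, class, tier),
so alternative counting conventions are reproducible by swapping the
table.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

from .numbering import CONSERVED_CYS, ImgtNumbering, RegionAnnotation, region_of
from .seqio import SequenceRecord

LIABILITY_CLASSES = (
    "n_glycosylation",
    "deamidation",
    "isomerization",
    "oxidation",
    "hydrolysis",
    "unpaired_cysteine",
)


@dataclass
class MotifRule:
    pattern: str
    liability_class: str
    risk_tier: str

    def __post_init__(self) -> None:
        if self.liability_class not in LIABILITY_CLASSES:
            raise ValueError(f"unknown liability class {self.liability_class!r}")
        if self.risk_tier not in ("high", "medium"):
            raise ValueError(f"unknown risk tier {self.risk_tier!r}")
        self.regex = re.compile(self.pattern)


@dataclass
class PTMSite:
    query_id: str
    position: int
    motif: str
    liability_class: str
    risk_tier: str
    region: Optional[str] = None


def load_motif_table(path=None) -> List[MotifRule]:
    """Load motif rules from a TSV; default is the bundled table."""
    if path is None:
        from .fixtures import load_motif_table_path

        with load_motif_table_path() as p:
            return load_motif_table(p)
    rules = []
    with open(Path(path)) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rules.append(
                MotifRule(
                    pattern=row["motif_regex"],
                    liability_class=row["liability_class"],
                    risk_tier=row["risk_tier"],
                )
            )
    return rules


_DEFAULT_RULES: Optional[List[MotifRule]] = None


def default_rules() -> List[MotifRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_motif_table()
    return _DEFAULT_RULES


def scan_ptm(
    rec: SequenceRecord,
    annotation: Optional[RegionAnnotation] = None,
    numbering: Optional[ImgtNumbering] = None,
    rules: Optional[Sequence[MotifRule]] = None,
) -> List[PTMSite]:
    """Scan a sequence for liability motifs.

    Deterministic left-to-right scan; overlapping matches are all
    reported. When ``annotation`` is supplied each site is tagged with
    its FR/CDR region. When ``numbering`` is supplied, cysteines outside
    the conserved IMGT 23/104 pair are additionally reported as
    high-risk ``unpaired_cysteine`` sites (one per residue); without
    numbering cysteines are left unclassified, since the conserved pair
    cannot be located.
    """
    rules = default_rules() if rules is None else rules
    seq = rec.seq
    region_at = None
    if annotation is not None:
        region_at = [None] * len(seq)
        for name, (s, e) in annotation.spans.items():
            for i in range(s, e):
                region_at[i] = name
    sites: List[PTMSite] = []
    for i in range(len(seq)):
        for rule in rules:
            m = rule.regex.match(seq, i)
            if m and m.start() == i:
                sites.append(
                    PTMSite(
                        query_id=rec.id,
                        position=i,
                        motif=m.group(0),
                        liability_class=rule.liability_class,
                        risk_tier=rule.risk_tier,
                        region=region_at[i] if region_at else None,
                    )
                )
    if numbering is not None:
        conserved_idx = {
            numbering.label_lookup().get((p, 0)) for p in CONSERVED_CYS
        }
        for i, c in enumerate(seq):
            if c == "C" and i not in conserved_idx:
                sites.append(
                    PTMSite(
                        query_id=rec.id,
                        position=i,
                        motif="C",
                        liability_class="unpaired_cysteine",
                        risk_tier="high",
                        region=region_at[i] if region_at else None,
                    )
                )
    sites.sort(key=lambda s: (s.position, s.liability_class))
    return sites


def count_high_risk(sites: Sequence[PTMSite]) -> int:
    """Number of sites in the high risk tier."""
    return sum(1 for s in sites if s.risk_tier == "high")
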