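"""IMGT numbering by anchor transfer and FR/CDR delimitation.

A query is aligned to its (best-matching) germline V-gene reference and
every reference-aligned residue inherits the reference's IMGT number.
Query insertions receive insertion codes on the preceding number. The
V gene ends at the second conserved cysteine (IMGT 104); the remaining
tail is split into CDR3 and FR4 by right-anchoring FR4 on the J-segment
motif ``WGQG`` (IMGT 118-121) and numbering the CDR3 loop by the IMGT
junction convention: positions 105-117, with gaps removed from the loop
apex for short loops and paired insertion codes 111.x / 112.x for long
ones.

This anchor-transfer scheme replaces profile-HMM numbering; it is exact
within the curated regime where every sequence is >85% identical to a
known reference.

IMGT region boundaries: CDR1 27-38, CDR2 56-65, CDR3 105-117; the
conserved cysteines sit at 23 (FR1) and 104 (FR3), the FR2 tryptophan at
41.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .germline import GermlineReference, align_global, percent_identity
from .seqio import SequenceRecord

# IMGT delimitation constants (inclusive position ranges)
CDR1_RANGE = (27, 38)
CDR2_RANGE = (56, 65)
CDR3_RANGE = (105, 117)
FR4_RANGE = (118, 128)
CONSERVED_CYS = (23, 104)
FR4_ANCHOR_MOTIF = "WGQG"

#: Minimum alignment identity for a sequence to be numberable at all.
NUMBERING_IDENTITY_FLOOR = 0.50

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

#: An IMGT label: (position, insertion_code); insertion_code 0 means none.
ImgtLabel = Tuple[int, int]


class UnnumberableError(ValueError):
    """Query too diverged from the reference to inherit its numbering."""


class RegionError(ValueError):
    """A region anchor position is missing from the numbering."""


def label_str(label: ImgtLabel) -> str:
    n, ins = label
    return f"{n}.{ins}" if ins else str(n)


def label_sort_key(label: ImgtLabel) -> Tuple[int, int]:
    """Canonical IMGT ordering of labels.

    Insertion codes sort after their base position (40 < 40.1 < 41),
    except the CDR3 apex block at 112 where they sort in descending code
    order *before* the base (111.2 < 112.2 < 112.1 < 112), mirroring the
    junction numbering convention.
    """
    n, ins = label
    if n == 112 and ins:
        return (n, -ins)
    return (n, ins) if ins == 0 else (n, ins)


def region_of(label: ImgtLabel) -> str:
    n = label[0]
    if n < CDR1_RANGE[0]:
        return "FR1"
    if n <= CDR1_RANGE[1]:
        return "CDR1"
    if n < CDR2_RANGE[0]:
        return "FR2"
    if n <= CDR2_RANGE[1]:
        return "CDR2"
    if n < CDR3_RANGE[0]:
        return "FR3"
    if n <= CDR3_RANGE[1]:
        return "CDR3"
    return "FR4"


@dataclass
class ImgtNumbering:
    """Per-residue IMGT labels for one query.

    ``positions[i] = (residue_index, label)`` in residue order; every
    residue appears exactly once and labels are non-decreasing under the
    canonical IMGT ordering.
    """

    query_id: str
    seq: str
    positions: List[Tuple[int, ImgtLabel]]
    reference: str = ""
    identity: float = 1.0

    def label_lookup(self) -> Dict[ImgtLabel, int]:
        """Mapping label -> residue index."""
        return {lab: i for i, lab in self.positions}

    def residue_at(self, position: int) -> Optional[str]:
        """Residue carrying integer IMGT ``position``, or None."""
        idx = self.label_lookup().get((position, 0))
        return self.seq[idx] if idx is not None else None


@dataclass
class RegionAnnotation:
    """FR/CDR spans tiling a query, as half-open residue-index intervals."""

    query_id: str
    seq: str
    spans: Dict[str, Tuple[int, int]]
    cdr1: str
    cdr2: str
    cdr3: str

    def region_seq(self, region: str) -> str:
        s, e = self.spans[region]
        return self.seq[s:e]


@dataclass
class DisulfideCheck:
    query_id: str
    has_c23: bool
    has_c104: bool

    @property
    def conserved_pair_present(self) -> bool:
        return self.has_c23 and self.has_c104


def cdr3_labels(length: int) -> List[ImgtLabel]:
    """IMGT junction labels for a CDR3 loop of ``length`` residues.

    Positions 105-117 hold up to 13 residues, filled from both ends with
    the extra residue on the N-terminal side; longer loops take paired
    insertion codes 111.1..111.a then 112.b..112.1 at the apex.
    """
    if length < 0:
        raise ValueError("negative CDR3 length")
    lo, hi = CDR3_RANGE
    cap = hi - lo + 1  # 13
    if length <= cap:
        n_left = (length + 1) // 2
        n_right = length - n_left
        left = [(lo + k, 0) for k in range(n_left)]
        right = [(hi - n_right + 1 + k, 0) for k in range(n_right)]
        return left + right
    extra = length - cap
    a = (extra + 1) // 2
    b = extra - a
    labels = [(lo + k, 0) for k in range(7)]          # 105..111
    labels += [(111, k) for k in range(1, a + 1)]      # 111.1..111.a
    labels += [(112, k) for k in range(b, 0, -1)]      # 112.b..112.1
    labels += [(112 + k, 0) for k in range(6)]         # 112..117
    return labels


def number_sequence(rec: SequenceRecord, ref: GermlineReference) -> ImgtNumbering:
    """Transfer IMGT numbering from ``ref`` onto ``rec`` by alignment.

    Raises :class:`UnnumberableError` when alignment identity falls below
    the floor (default 0.50): anchor transfer is only trustworthy near the
    reference.
    """
    aln = align_global(rec.seq, ref.seq)
    ident = percent_identity(aln)
    if ident < NUMBERING_IDENTITY_FLOOR:
        raise UnnumberableError(
            f"{rec.id}: identity {ident:.2f} to {ref.name} below "
            f"{NUMBERING_IDENTITY_FLOOR} — unnumberable"
        )
    ref_numbers = [g for _, g in ref.imgt_map]
    labels: List[Optional[ImgtLabel]] = [None] * len(rec.seq)
    qi = ri = 0
    last_ref_number: Optional[int] = None
    pending_insertions: List[int] = []  # query indices awaiting a code
    leading: List[int] = []
    last_aligned_qi = -1
    for qc, rc in zip(aln.aligned_query, aln.aligned_reference):
        if qc != "-" and rc != "-":
            # flush insertions accumulated since the previous anchor
            if pending_insertions:
                for k, idx in enumerate(pending_insertions, start=1):
                    labels[idx] = (last_ref_number, k)
                pending_insertions = []
            labels[qi] = (ref_numbers[ri], 0)
            last_ref_number = ref_numbers[ri]
            last_aligned_qi = qi
            qi += 1
            ri += 1
        elif qc != "-":
            if last_ref_number is None:
                leading.append(qi)
            else:
                pending_insertions.append(qi)
            qi += 1
        else:
            ri += 1
    if last_ref_number is None:
        raise UnnumberableError(f"{rec.id}: no residue aligned to {ref.name}")
    # residues hanging off the N-terminus count back from the first number
    if leading:
        first_number = next(lab[0] for lab in labels if lab is not None)
        for k, idx in enumerate(reversed(leading), start=1):
            n = first_number - k
            if n < 1:
                raise UnnumberableError(
                    f"{rec.id}: {len(leading)} residues overhang IMGT position 1"
                )
            labels[idx] = (n, 0)
    # tail past the last reference-aligned residue: CDR3 + FR4
    tail_start = last_aligned_qi + 1
    tail = rec.seq[tail_start:]
    if tail:
        if last_ref_number >= CONSERVED_CYS[1]:
            w = tail.rfind(FR4_ANCHOR_MOTIF)
            if w >= 0:
                for lab, idx in zip(
                    cdr3_labels(w), range(tail_start, tail_start + w)
                ):
                    labels[idx] = lab
                for k in range(len(tail) - w):
                    labels[tail_start + w + k] = (FR4_RANGE[0] + k, 0)
            else:
                for k in range(len(tail)):
                    labels[tail_start + k] = (last_ref_number + 1 + k, 0)
        else:
            # truncated before 104: continue by distance from the last anchor
            for k in range(len(tail)):
                labels[tail_start + k] = (last_ref_number + 1 + k, 0)
    assert all(lab is not None for lab in labels)
    positions = [(i, lab) for i, lab in enumerate(labels)]
    keys = [label_sort_key(lab) for _, lab in positions]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise UnnumberableError(f"{rec.id}: numbering not monotone (alignment artefact)")
    return ImgtNumbering(
        query_id=rec.id,
        seq=rec.seq,
        positions=positions,
        reference=ref.name,
        identity=ident,
    )


def extract_regions(numbering: ImgtNumbering) -> RegionAnnotation:
    """Delimit FR1..FR4 / CDR1..CDR3 from an IMGT numbering.

    The spans are contiguous, non-overlapping and tile the whole query.
    Raises :class:`RegionError` when a CDR's flanking anchor positions
    are absent (e.g. a sequence truncated before IMGT 105 has no CDR3).
    """
    lookup = {lab: i for i, lab in numbering.positions}
    anchors = {
        "CDR1": (CDR1_RANGE[0] - 1, CDR1_RANGE[1] + 1),
        "CDR2": (CDR2_RANGE[0] - 1, CDR2_RANGE[1] + 1),
        "CDR3": (CDR3_RANGE[0] - 1, CDR3_RANGE[1] + 1),
    }
    for region, (left, right) in anchors.items():
        if (left, 0) not in lookup or (right, 0) not in lookup:
            missing = [p for p in (left, right) if (p, 0) not in lookup]
            raise RegionError(
                f"{numbering.query_id}: missing anchor position(s) "
                f"{missing} flanking {region}"
            )
    regions = [region_of(lab) for _, lab in numbering.positions]
    order = {name: k for k, name in enumerate(REGION_ORDER)}
    if any(order[b] < order[a] for a, b in zip(regions, regions[1:])):
        raise RegionError(f"{numbering.query_id}: region order violated")
    spans: Dict[str, Tuple[int, int]] = {}
    start = 0
    for name in REGION_ORDER:
        end = start
        while end < len(regions) and regions[end] == name:
            end += 1
        spans[name] = (start, end)
        start = end
    seq = numbering.seq
    return RegionAnnotation(
        query_id=numbering.query_id,
        seq=seq,
        spans=spans,
        cdr1=seq[spans["CDR1"][0]:spans["CDR1"][1]],
        cdr2=seq[spans["CDR2"][0]:spans["CDR2"][1]],
        cdr3=seq[spans["CDR3"][0]:spans["CDR3"][1]],
    )


def check_conserved_cysteines(numbering: ImgtNumbering) -> DisulfideCheck:
    """Report whether the residues at IMGT 23 and 104 exist and are Cys."""
    return DisulfideCheck(
        query_id=numbering.query_id,
        has_c23=numbering.residue_at(CONSERVED_CYS[0]) == "C",
        has_c104=numbering.residue_at(CONSERVED_CYS[1]) == "C",
    )


def numbering_to_rows(numbering: ImgtNumbering) -> List[Tuple[str, int, str, str]]:
    """Flatten a numbering to (query_id, residue_index, residue, imgt_label)."""
    return [
        (numbering.query_id, i, numbering.seq[i], label_str(lab))
        for i, lab in numbering.positions
    ]
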