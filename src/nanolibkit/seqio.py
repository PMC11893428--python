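"""Sequence I/O and validation.

The record unit throughout the toolkit is a plain amino-acid sequence over
the 20 canonical residues, optionally tagged with the germline it derives
from. Ambiguity codes (X/B/Z) and stops (*) are rejected outright rather
than masked: downstream positional frequency statistics would be poisoned
by placeholder letters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass
class SequenceRecord:
    """A validated amino-acid sequence.

    Attributes
    ----------
    id : str
        Unique identifier within any collection produced by a reader.
    seq : str
        Uppercase amino-acid string over the 20-letter alphabet.
    germline_label : str, optional
        Germline assignment, e.g. ``"IGHV3-3*01"``.
    """

    id: str
    seq: str
    germline_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ValidationVerdict:
    """Outcome of :func:`validate_sequence`.

    ``violations`` lists ``(position, character)`` pairs for every residue
    outside the canonical alphabet; ``ok`` is true iff the list is empty.
    """

    violations: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_sequence(seq: str) -> ValidationVerdict:
    """Check a sequence against the 20-letter amino-acid alphabet.

    Never raises; every offending character is reported with its 0-based
    position. The empty string is reported as a violation at position 0.
    """
    if not seq:
        return ValidationVerdict(violations=[(0, "")])
    bad = [(i, c) for i, c in enumerate(seq) if c not in _AA_SET]
    return ValidationVerdict(violations=bad)


def _parse_germline(description: str) -> Optional[str]:
    for tok in description.split():
        if tok.startswith("germline="):
            return tok[len("germline="):]
    return None


def read_fasta(path) -> List[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; sequences are uppercased; duplicate IDs are
    deduplicated by suffixing ``.2``, ``.3`` ... in order of appearance.
    A ``germline=NAME`` token in the description is picked up as the
    record's germline label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    seen: dict = {}
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending content
        raise FastaParseError(f"{path}: {exc}") from exc
    # Biopython silently yields nothing for garbage lacking '>': detect.
    if not entries:
        text = path.read_text().strip()
        if text and not text.startswith(">"):
            first = text.splitlines()[0]
            raise FastaParseError(
                f"{path}: not FASTA — first line {first!r} does not start with '>'"
            )
        logger.warning("read_fasta: %s contains no sequences", path)
        return []
    for entry in entries:
        rid = entry.id
        if rid in seen:
            seen[rid] += 1
            rid = f"{rid}.{seen[entry.id]}"
        else:
            seen[rid] = 1
        records.append(
            SequenceRecord(
                id=rid,
                seq=str(entry.seq).upper(),
                germline_label=_parse_germline(entry.description),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records to FASTA with 60-column wrapping.

    Round-trip safe with :func:`read_fasta` on ids and sequences.
    """
    path = Path(path)
    bio = []
    for rec in records:
        desc = f"germline={rec.germline_label}" if rec.germline_label else ""
        bio.append(_BioSeqRecord(Seq(rec.seq), id=rec.id, description=desc))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)
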