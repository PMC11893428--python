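"""Bundled reference data.

Two alpaca-style germline V-gene references (IGHV3-3*01 and IGHV3S53*01
backbones) with hand-assigned IMGT position maps, and the two full-length
frameworks chosen for library construction. The references span IMGT
positions 1-104, ending at the second conserved cysteine; their maps carry
the standard IGHV3 gaps (position 10 absent in FR1, position 73 absent in
FR3, CDR1/CDR2 gapped toward the loop apex).
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict, List

from .germline import GermlineReference
from .seqio import SequenceRecord, read_fasta

#: Names of the two bundled germlines, in deterministic order.
GERMLINES = ("IGHV3-3*01", "IGHV3S53*01")


def _data_path(name: str):
    return resources.files("nanolibkit.data").joinpath(name)


def load_frameworks() -> Dict[str, SequenceRecord]:
    """The two full library frameworks, keyed by germline name."""
    with resources.as_file(_data_path("frameworks.fasta")) as p:
        recs = read_fasta(p)
    return {r.germline_label: r for r in recs}


def load_references() -> List[GermlineReference]:
    """The bundled germline V-gene references with their IMGT maps."""
    with resources.as_file(_data_path("germline_refs.fasta")) as p:
        recs = {r.id: r for r in read_fasta(p)}
    maps: Dict[str, List[tuple]] = {name: [] for name in recs}
    with _data_path("germline_refs.imgt.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            maps[row["germline"]].append(
                (int(row["residue_index"]), int(row["imgt_position"]))
            )
    refs = []
    for name in GERMLINES:
        refs.append(
            GermlineReference(name=name, seq=recs[name].seq, imgt_map=sorted(maps[name]))
        )
    return refs


def load_motif_table_path():
    """Filesystem path context for the default PTM motif table."""
    return resources.as_file(_data_path("ptm_motifs.tsv"))
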