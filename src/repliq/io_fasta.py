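"""FASTA input/output for template strands (Biopython SeqIO backend).

Records are uppercased on read; any character outside {A, C, G, T} (ambiguity
codes included) is rejected with the record and 1-based position named, since
the replication model is defined on exactly four symbols.
"""

from __future__ import annotations

import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import SYMBOL_INDEX, TemplateSequence


def read_fasta(path: str | os.PathLike) -> list[TemplateSequence]:
    """Read all records of a FASTA file as template strands."""
    templates: list[TemplateSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in SYMBOL_INDEX:
                raise ValueError(
                    f"record {record.id!r} in {path}: invalid symbol {ch!r} at "
                    f"position {pos} (only A, C, G, T are allowed)"
                )
        if not seq:
            raise ValueError(f"record {record.id!r} in {path} is empty")
        templates.append(TemplateSequence(seq, label=record.id))
    if not templates:
        raise ValueError(f"no FASTA records found in {path}")
    return templates


def write_fasta(templates, path: str | os.PathLike) -> None:
    """Write template (or copied) strands to FASTA; round-trips with read_fasta."""
    records = [
        SeqRecord(Seq(t.symbols), id=getattr(t, "label", getattr(t, "template_label", "seq")), description="")
        for t in templates
    ]
    SeqIO.write(records, str(path), "fasta")
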