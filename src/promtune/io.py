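"""FASTA and TSV plumbing shared by the CLI and the examples."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import PromoterSequence


def read_genome(path: str | Path, record_id: str | None = None) -> str:
    """Return the sequence of one FASTA record (the first unless an id is given)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return str(rec.seq).upper()
    raise ValueError(f"no record {record_id!r} in {path}" if record_id else f"no records in {path}")


def read_promoters(path: str | Path) -> list[PromoterSequence]:
    """Read every record of a FASTA file as a PromoterSequence."""
    promoters = [
        PromoterSequence(bases=str(rec.seq), id=rec.id) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not promoters:
        raise ValueError(f"no records in {path}")
    return promoters


def write_promoters(promoters: list[PromoterSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.bases), id=p.id or f"promoter_{i}", description="")
        for i, p in enumerate(promoters)
    ]
    SeqIO.write(records, str(path), "fasta")
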