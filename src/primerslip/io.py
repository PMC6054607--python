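"""FASTA/FASTQ/TSV input-output helpers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import DegeneratePrimer
from .synth import Read

__all__ = [
    "read_primers",
    "write_primers",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_tsv",
]


def read_primers(path) -> list[DegeneratePrimer]:
    """Load IUPAC primers from FASTA; orientation from an ``orientation=`` header key."""
    primers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        orientation = None
        for token in rec.description.split():
            if token.startswith("orientation="):
                orientation = token.split("=", 1)[1]
        if orientation is None:
            raise ValueError(
                f"primer record {rec.id!r}: missing 'orientation=forward|reverse' header key"
            )
        primers.append(DegeneratePrimer(rec.id, str(rec.seq), orientation))
    if not primers:
        raise ValueError(f"no primer records in {path}")
    return primers


def write_primers(path, primers: list[DegeneratePrimer]) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.name, description=f"orientation={p.orientation}")
        for p in primers
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Multi-FASTA as an id -> sequence dict; duplicate ids are rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=tid, description="") for tid, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """FASTQ as (id, sequence, quality-string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, reads: list[Read]) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_tsv(path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    """TSV with an optional leading ``#`` comment line (config provenance)."""
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
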