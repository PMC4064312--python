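"""FASTA/FASTQ read-set IO (Biopython-backed)."""
from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_reads(reads, path, fmt: str = "fasta", quality: int = 35) -> None:
    """Write (name, sequence) pairs; FASTQ gets a flat Sanger quality."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, fmt)


def read_reads(path, fmt: str | None = None) -> list[tuple[str, str]]:
    if fmt is None:
        fmt = "fastq" if str(path).endswith((".fq", ".fastq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def read_fasta_windows(path) -> dict[str, str]:
    """Reference windows keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
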