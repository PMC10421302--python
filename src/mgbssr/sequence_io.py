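"""Genome I/O: FASTA reading/writing, subsequence access, locus tables.

All in-memory coordinates are 0-based half-open. Exported locus tables use
1-based inclusive positions (GFF3 convention) and say so in their header.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "subsequence",
    "reverse_complement",
    "write_locus_table",
    "read_locus_table",
    "write_gff3",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
# IUPAC ambiguity letters are accepted on input but collapsed to N.
_IUPAC_EXTRA = set("RYSWKMBDHVU")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


@dataclass
class GenomeSequence:
    """One genome assembly: a label plus an ordered map of sequence records.

    Sequences are stored uppercase; any letter outside A/C/G/T/N is
    collapsed to N on construction.
    """

    genome_label: str
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for seq_id, seq in self.records.items():
            clean[seq_id] = _sanitize(seq, where=f"record {seq_id!r}")
        self.records = clean

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]


def _sanitize(seq: str, where: str = "sequence") -> str:
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    out = []
    for ch in s:
        if ch in _VALID:
            out.append(ch)
        elif ch in _IUPAC_EXTRA:
            out.append("N")
        else:
            raise FastaFormatError(f"non-nucleotide character {ch!r} in {where}")
    return "".join(out)


def _open_text(path: str | os.PathLike):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _validate_fasta_lines(path: str | os.PathLike) -> None:
    """Cheap pre-pass so errors can name the offending line number."""
    seen: set[str] = set()
    n_headers = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                n_headers += 1
                seq_id = stripped[1:].split()[0] if len(stripped) > 1 else ""
                if not seq_id:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                if seq_id in seen:
                    raise FastaFormatError(
                        f"{path}: duplicate sequence id {seq_id!r} at line {lineno}"
                    )
                seen.add(seq_id)
            elif n_headers == 0:
                raise FastaFormatError(
                    f"{path}: line {lineno} precedes any '>' header; not FASTA"
                )
    if n_headers == 0:
        raise FastaFormatError(f"{path}: empty file or no FASTA records")


def read_fasta(path: str | os.PathLike, genome_label: str | None = None) -> GenomeSequence:
    """Read a (optionally gzipped) multi-FASTA file into a :class:`GenomeSequence`.

    The genome label defaults to the file's base name without extensions.
    """
    _validate_fasta_lines(path)
    if genome_label is None:
        base = os.path.basename(str(path))
        for ext in (".gz", ".fa", ".fasta", ".fna"):
            if base.endswith(ext):
                base = base[: -len(ext)]
        genome_label = base
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records[rec.id] = str(rec.seq)
    return GenomeSequence(genome_label=genome_label, records=records)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for seq_id, seq in genome.records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def subsequence(genome: GenomeSequence, seq_id: str, start: int, end: int) -> str:
    """Return genome[seq_id][start:end] (0-based half-open), with bounds checks."""
    if seq_id not in genome.records:
        raise KeyError(f"unknown sequence id {seq_id!r} in genome {genome.genome_label!r}")
    seq = genome.records[seq_id]
    if not (0 <= start <= end <= len(seq)):
        raise IndexError(
            f"interval [{start}, {end}) out of range for {seq_id!r} (length {len(seq)})"
        )
    return seq[start:end]


def reverse_complement(s: str) -> str:
    """Reverse complement of an A/C/G/T/N string (involution; N maps to N)."""
    s = s.upper()
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


_LOCUS_COLUMNS = ["genome", "seq_id", "start", "end", "motif", "repeat_count", "core_seq"]


def write_locus_table(loci: Iterable, path: str | os.PathLike) -> None:
    """Write SSR loci as TSV with 1-based inclusive coordinates."""
    with open(path, "wt") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("\t".join(_LOCUS_COLUMNS) + "\n")
        for loc in loci:
            fh.write(
                "\t".join(
                    [
                        loc.genome_label,
                        loc.seq_id,
                        str(loc.start + 1),
                        str(loc.end),
                        loc.motif,
                        str(loc.repeat_count),
                        loc.core_seq,
                    ]
                )
                + "\n"
            )


def read_locus_table(path: str | os.PathLike):
    """Read a locus TSV written by :func:`write_locus_table`."""
    from .ssr_detection import SSRLocus

    loci = []
    with open(path, "rt") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            loci.append(
                SSRLocus(
                    genome_label=row["genome"],
                    seq_id=row["seq_id"],
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    motif=row["motif"],
                    repeat_count=int(row["repeat_count"]),
                )
            )
    return loci


def write_gff3(loci: Iterable, path: str | os.PathLike, source: str = "mgbssr") -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, loc in enumerate(loci, start=1):
            attrs = f"ID=ssr{i};motif={loc.motif};repeat_count={loc.repeat_count}"
            fh.write(
                "\t".join(
                    [
                        loc.seq_id,
                        source,
                        "microsatellite",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
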