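"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; FASTQ and BED use small strict parsers that
report the file position of any malformed record. BED intervals are
0-based half-open. FASTQ qualities are Sanger Phred+33.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Iterator, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._intervals import GenomeIntervals


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str  # Phred+33 string, same length as sequence

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode("ascii"), dtype=np.uint8) - 33


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Sequences by name, uppercased. Tolerates CRLF line endings."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Yield reads, validating record structure with line-positioned errors."""
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\r\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not qual and not plus:
                raise ValueError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno - 1}: expected '+' separator line")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield FastqRead(header[1:].split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> GenomeIntervals:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid BED interval [{start}, {end})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
    return GenomeIntervals(by_chrom)


def write_bed(rows: Iterable[Sequence], path: str | Path) -> None:
    """Write rows of (chrom, start, end[, name[, score]]) as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(frame: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
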