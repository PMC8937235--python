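"""Streaming sequence and table I/O.

Reads FASTQ or FASTA, plain or gzip-compressed, auto-detected by content
(gzip magic bytes, then ``@``/``>`` on the first record line).  Sequences
are normalized to uppercase DNA (U→T) at ingest; records stream one at a
time so arbitrarily large files can be processed.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import normalize_seq

__all__ = ["Read", "ParseError", "read_sequences", "write_fastq", "write_table"]

PathLike = Union[str, Path]


class Read(NamedTuple):
    """A sequencing read reduced to identifier + normalized sequence."""

    id: str
    seq: str


class ParseError(ValueError):
    """A sequence file was malformed; the message names the record index."""


def _open_maybe_gzip(path: PathLike) -> IO[str]:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return _io.TextIOWrapper(fh)


def read_sequences(path: PathLike) -> Iterator[Read]:
    """Stream reads from a FASTQ/FASTA file (optionally gzipped)."""
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == "":
            return
        if first == "@":
            n = 0
            try:
                for title, seq, _qual in FastqGeneralIterator(handle):
                    n += 1
                    yield Read(title.split()[0], normalize_seq(seq))
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record {n + 1} in {path}: {exc}") from exc
        elif first == ">":
            n = 0
            try:
                for title, seq in SimpleFastaParser(handle):
                    n += 1
                    yield Read(title.split()[0], normalize_seq(seq))
            except ValueError as exc:
                raise ParseError(f"malformed FASTA record {n + 1} in {path}: {exc}") from exc
        else:
            raise ParseError(f"{path}: first record starts with {first!r}; expected '@' or '>'")


def write_fastq(reads: Iterable[Read], path: PathLike, quality_char: str = "I") -> int:
    """Write reads as FASTQ with a constant quality string; returns count.

    Gzip-compresses when the path ends in ``.gz`` (with mtime pinned to 0 so
    identical inputs give byte-identical archives).
    """
    path = str(path)
    n = 0
    if path.endswith(".gz"):
        raw = open(path, "wb")
        handle: IO[str] = _io.TextIOWrapper(
            gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
        )
    else:
        handle = open(path, "w")
    with handle:
        for r in reads:
            handle.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")
            n += 1
    return n


def write_table(frame: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """Write a DataFrame as tab-separated UTF-8 with a header row."""
    frame.to_csv(path, sep="\t", index=index)
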