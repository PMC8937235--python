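"""Read decoding: demultiplexing, primer anchoring, triplet segmentation.

A raw read has the layout ``[sample barcode] + primer + extension + [3'
adapter + downstream]``.  Decoding reduces it to an ordered list of triplet
calls: the primer is located by exact substring search, the extension is
read off in a non-overlapping triplet frame from the base after the primer,
and the first occurrence of the 3' adapter (prefix ``GTCGAATAT``) marks the
end of the ribozyme-made product.  All matching is exact by default — the
fidelity statistics downstream are defined over exact matches — with an
optional Hamming tolerance for sample barcodes only.

Reads are processed in the deposited (product-strand) orientation; there is
no reverse-complement search unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import Read
from .model import ConfigError, Triplet, normalize_seq

__all__ = [
    "DecodedRead",
    "DecodeResult",
    "DEFAULT_ADAPTER",
    "demultiplex",
    "anchor_and_trim",
    "segment_triplets",
    "decode_reads",
    "write_decoded",
    "read_decoded",
]

#: Prefix of the ligated 3' adapter as it appears in the sequenced product.
DEFAULT_ADAPTER = "GTCGAATAT"


@dataclass(frozen=True)
class DecodedRead:
    """A read reduced to triplet calls at positions ``1..k``.

    ``frame_ok`` is False only when the adapter was found off the triplet
    frame (such reads cannot be assigned triplet positions and are excluded
    from fidelity counting); when no adapter is present the frame is not
    contradicted and the flag stays True.  ``trailing_bases`` holds the 0–2
    residual letters left over after the last complete triplet.
    """

    read_id: str
    sample_id: Optional[str]
    triplets: tuple[Triplet, ...]
    adapter_found: bool
    frame_ok: bool
    trailing_bases: str = ""

    @property
    def k(self) -> int:
        return len(self.triplets)


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def demultiplex(
    reads: Iterable[Read],
    barcode_table: Mapping[str, str],
    max_mismatches: int = 0,
) -> dict[str, list[Read]]:
    """Group reads by exact (or Hamming-tolerant) sample-barcode prefix.

    Returns ``{sample_id: [reads...]}`` with an extra ``"unmatched"`` bin;
    every input read lands in exactly one bin.
    """
    table = {normalize_seq(bc): sid for bc, sid in barcode_table.items()}
    if len(table) != len(barcode_table):
        raise ConfigError("duplicate sample barcodes")
    lengths = {len(bc) for bc in table}
    if len(lengths) > 1:
        raise ConfigError("sample barcodes must have equal length")
    (bc_len,) = lengths or {0}
    out: dict[str, list[Read]] = {sid: [] for sid in table.values()}
    out.setdefault("unmatched", [])
    for read in reads:
        prefix = read.seq[:bc_len]
        target = "unmatched"
        if max_mismatches == 0:
            target = table.get(prefix, "unmatched")
        else:
            for bc, sid in table.items():
                if len(prefix) == bc_len and _hamming_leq(prefix, bc, max_mismatches):
                    target = sid
                    break
        out[target].append(read)
    return out


def anchor_and_trim(seq: str, primer_seq: str) -> Optional[str]:
    """Everything after the first exact primer occurrence, or None.

    Reads without the primer are excluded from analysis (the caller counts
    them).  When the primer occurs more than once only the first occurrence
    anchors the frame.
    """
    if not primer_seq:
        raise ConfigError("primer must be non-empty")
    idx = seq.find(primer_seq)
    if idx < 0:
        return None
    return seq[idx + len(primer_seq) :]


def segment_triplets(
    ext_seq: str, adapter_seq: str = DEFAULT_ADAPTER
) -> tuple[tuple[Triplet, ...], bool, bool, str]:
    """Split an extension sequence into non-overlapping triplets.

    Returns ``(triplets, adapter_found, frame_ok, trailing_bases)``.  The
    first adapter occurrence ends the product; triplets are read in frame
    from position 1 up to the adapter start (or the end of the read), and
    whatever does not fill a complete triplet is reported as trailing bases.
    """
    idx = ext_seq.find(adapter_seq) if adapter_seq else -1
    if idx >= 0:
        region = ext_seq[:idx]
        adapter_found = True
        frame_ok = idx % 3 == 0
    else:
        region = ext_seq
        adapter_found = False
        frame_ok = True
    n_full = len(region) // 3
    triplets = tuple(Triplet(region[3 * i : 3 * i + 3]) for i in range(n_full))
    trailing = region[3 * n_full :]
    return triplets, adapter_found, frame_ok, trailing


@dataclass
class DecodeResult:
    """Decoded reads grouped by sample plus bookkeeping counts."""

    by_sample: dict[Optional[str], list[DecodedRead]]
    summary: dict

    @property
    def decoded(self) -> list[DecodedRead]:
        return [d for group in self.by_sample.values() for d in group]


def decode_reads(
    reads: Iterable[Read],
    primer_seq: str,
    adapter_seq: str = DEFAULT_ADAPTER,
    barcode_table: Optional[Mapping[str, str]] = None,
    max_mismatches: int = 0,
    search_reverse_complement: bool = False,
) -> DecodeResult:
    """Full decoding pass: demultiplex (optional), anchor, segment.

    Conservation: assigned + unmatched + primer-less = total input reads
    (the summary records every bin).
    """
    primer_seq = normalize_seq(primer_seq)
    adapter_seq = normalize_seq(adapter_seq)
    reads = list(reads)
    total = len(reads)
    if barcode_table is not None:
        groups: dict[Optional[str], list[Read]] = dict(
            demultiplex(reads, barcode_table, max_mismatches)
        )
    else:
        groups = {None: reads}

    by_sample: dict[Optional[str], list[DecodedRead]] = {}
    no_primer = 0
    multi_primer = 0
    frame_shifted = 0
    unmatched = len(groups.get("unmatched", [])) if barcode_table is not None else 0
    for sample, group in groups.items():
        if sample == "unmatched":
            continue
        decoded: list[DecodedRead] = []
        for read in group:
            seq = read.seq
            ext = anchor_and_trim(seq, primer_seq)
            if ext is None and search_reverse_complement:
                ext = anchor_and_trim(_reverse_complement(seq), primer_seq)
            if ext is None:
                no_primer += 1
                continue
            if seq.count(primer_seq) > 1:
                multi_primer += 1
            triplets, adapter_found, frame_ok, trailing = segment_triplets(ext, adapter_seq)
            if adapter_found and not frame_ok:
                frame_shifted += 1
            decoded.append(
                DecodedRead(
                    read_id=read.id,
                    sample_id=sample,
                    triplets=triplets,
                    adapter_found=adapter_found,
                    frame_ok=frame_ok,
                    trailing_bases=trailing,
                )
            )
        by_sample[sample] = decoded
    summary = {
        "total_reads": total,
        "unmatched": unmatched,
        "no_primer": no_primer,
        "decoded": sum(len(v) for v in by_sample.values()),
        "multiple_primer_occurrences": multi_primer,
        "adapter_off_frame": frame_shifted,
        "per_sample": {str(s): len(v) for s, v in by_sample.items()},
    }
    return DecodeResult(by_sample=by_sample, summary=summary)


# -- tabular round-trip -------------------------------------------------


def write_decoded(decoded: Sequence[DecodedRead], path) -> None:
    """Write decoded reads as TSV (one row per read, triplets comma-joined)."""
    frame = pd.DataFrame(
        {
            "read_id": [d.read_id for d in decoded],
            "sample_id": [d.sample_id if d.sample_id is not None else "" for d in decoded],
            "k": [d.k for d in decoded],
            "triplets": [",".join(d.triplets) for d in decoded],
            "adapter_found": [int(d.adapter_found) for d in decoded],
            "frame_ok": [int(d.frame_ok) for d in decoded],
            "trailing_bases": [d.trailing_bases for d in decoded],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_decoded(path) -> list[DecodedRead]:
    """Read back a decoded-reads TSV written by :func:`write_decoded`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        trips = tuple(Triplet(t) for t in row.triplets.split(",")) if row.triplets else ()
        out.append(
            DecodedRead(
                read_id=row.read_id,
                sample_id=row.sample_id or None,
                triplets=trips,
                adapter_found=bool(int(row.adapter_found)),
                frame_ok=bool(int(row.frame_ok)),
                trailing_bases=row.trailing_bases,
            )
        )
    return out
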