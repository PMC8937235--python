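"""Length spectrum of fully correct concatemeric RCS products.

For branched rolling-circle synthesis the readout is the number of reads
that are a *complete, fully correct* product of each length: exactly ``k``
triplets, every one equal to the product's expected triplet at that
position, terminated by the 3' adapter on the triplet frame (the adapter
marks the genuine product end; a read without it could be a truncated
sequence of a longer molecule).  The spectrum maps each ``k`` to a read
count, product length in nt, and circle coverage (how many tandem copies
of the circular template the product spans).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import pandas as pd

from .decode import DecodedRead
from .model import (
    GeometryError,
    ProductSpec,
    TemplateSpec,
    circle_coverage,
    expected_triplet,
    product_length_nt,
)

__all__ = ["count_correct_products", "spectrum_summary"]

SpecLike = Union[ProductSpec, TemplateSpec]


def count_correct_products(
    decoded: Iterable[DecodedRead],
    products: Sequence[SpecLike],
    k_range: Sequence[int] = range(9, 31),
    require_adapter: bool = True,
) -> pd.DataFrame:
    """Spectrum table with columns product, k, n, length_nt, circle_coverage.

    Every read is tested against every product independently; a read whose
    triplets match more than one product (possible at small ``k`` when
    expected prefixes coincide) is counted for each and tallied in
    ``frame.attrs["ambiguous_reads"]``.  ``require_adapter=False`` drops
    the complete-product requirement (for sensitivity checks only).
    """
    k_range = list(k_range)
    for product in products:
        for k in k_range:
            if expected_triplet(product, k) is None:
                raise GeometryError(
                    f"product {product.name!r} has no expected triplet at position {k}"
                )
    counts = {(p.name, k): 0 for p in products for k in k_range}
    ambiguous = 0
    for read in decoded:
        if require_adapter:
            ok = read.adapter_found and read.frame_ok
        else:
            ok = read.frame_ok
        if not ok or read.k not in k_range:
            continue
        hits = [
            p
            for p in products
            if all(
                read.triplets[a - 1] == expected_triplet(p, a) for a in range(1, read.k + 1)
            )
        ]
        if len(hits) > 1:
            ambiguous += 1
        for p in hits:
            counts[(p.name, read.k)] += 1
    rows = []
    for p in products:
        circ = p.circle_len_nt
        for k in k_range:
            length = product_length_nt(p.primer_len_nt, k)
            rows.append(
                {
                    "product": p.name,
                    "k": k,
                    "n": counts[(p.name, k)],
                    "length_nt": length,
                    "circle_coverage": circle_coverage(length, circ) if circ else float("nan"),
                }
            )
    frame = pd.DataFrame(rows, columns=["product", "k", "n", "length_nt", "circle_coverage"])
    frame.attrs["ambiguous_reads"] = ambiguous
    return frame


def spectrum_summary(table: pd.DataFrame) -> dict:
    """Longest observed fully correct product per product and overall.

    Returns ``{"per_product": {name: {max_k, length_nt, circle_coverage,
    n_at_max}}, "overall": {...}}``; products with no positive count report
    ``max_k = None``.
    """
    if table.empty:
        raise ValueError("empty spectrum table")
    per_product: dict[str, dict] = {}
    best = None
    for name, sub in table.groupby("product", sort=True):
        hits = sub[sub["n"] > 0]
        if hits.empty:
            per_product[name] = {
                "max_k": None, "length_nt": None, "circle_coverage": None, "n_at_max": 0,
            }
            continue
        row = hits.loc[hits["k"].idxmax()]
        entry = {
            "max_k": int(row["k"]),
            "length_nt": int(row["length_nt"]),
            "circle_coverage": float(row["circle_coverage"]),
            "n_at_max": int(row["n"]),
        }
        per_product[name] = entry
        if best is None or entry["max_k"] > best["max_k"]:
            best = {"product": name, **entry}
    return {"per_product": per_product, "overall": best}
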