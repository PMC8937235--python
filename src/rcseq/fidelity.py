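"""Per-position incorporation fidelity on barcoded templates.

Reads from a one-pot experiment (all templates mixed) are attributed to a
template by the identifying barcode triplet at position 3 — so position 3
has 100% fidelity for the correct triplet by construction — and then
counted position by position.  Counting is *prefix-conditional* by
default: a read contributes at position ``a`` only when its triplets at
positions ``1..a-1`` all equal the template's expected triplets.  Fidelity
at ``(a, Y)`` is the percentage of counted reads carrying each alphabet
triplet,

    F(a, xxx, Y) = 100 * n(xxx, a, Y) / sum over the alphabet of n(XXX, a, Y)

Out-of-alphabet triplets (possible sequencing artifacts) are tallied
separately and excluded from the denominator, which sums over the offered
substrate alphabet only.  Cells with a denominator at or below a mask
threshold (default n ≤ 5) are flagged as unreliable.

With prefix conditioning the product of the correct-triplet fidelities
from position 3 through X telescopes exactly to the fraction of classified
reads that are fully correct through X — the cumulative probability of
templated synthesis — and the circular/linear ratio of those cumulative
probabilities is the fold advantage of a circular template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .decode import DecodedRead
from .model import (
    DEFAULT_ALPHABET,
    ConfigError,
    TemplateSpec,
    Triplet,
    TripletAlphabet,
    expected_triplet,
)

__all__ = [
    "CountMatrix",
    "FidelityMatrix",
    "classify_template",
    "count_conditional",
    "fidelity",
    "cumulative_correct",
    "fold_difference",
    "DEFAULT_POSITIONS",
    "BARCODE_POSITION",
    "MASK_THRESHOLD",
]

#: Position of the classifying barcode triplet.
BARCODE_POSITION = 3
#: Positions analyzed by default (barcode position through 2x full length).
DEFAULT_POSITIONS = range(3, 19)
#: Cells with n at or below this are masked as unreliable.
MASK_THRESHOLD = 5


def classify_template(
    read: DecodedRead, barcode_map: Mapping[Triplet, str]
) -> Optional[str]:
    """Template attribution by the barcode triplet at position 3, or None."""
    if len(set(barcode_map)) != len(barcode_map):
        raise ConfigError("barcode_map keys must be distinct")
    if read.k < BARCODE_POSITION:
        return None
    return barcode_map.get(read.triplets[BARCODE_POSITION - 1])


@dataclass
class CountMatrix:
    """Raw counts ``n(xxx, a, Y)`` over positions × alphabet × templates.

    ``n_total[(a, Y)]`` sums counts over the alphabet; ``other[(a, Y)]``
    tallies observed out-of-alphabet triplets (excluded from ``n_total``).
    ``n_classified[Y]`` is the number of reads attributed to each template.
    """

    counts: dict[tuple[int, Triplet, str], int]
    n_total: dict[tuple[int, str], int]
    other: dict[tuple[int, str], int]
    n_classified: dict[str, int]
    positions: tuple[int, ...]
    templates: tuple[str, ...]
    alphabet: TripletAlphabet
    conditioning: str
    specs: Mapping[str, TemplateSpec] = field(default_factory=dict)
    n_unclassified: int = 0

    def n(self, a: int, xxx: Triplet, Y: str) -> int:
        return self.counts.get((a, Triplet(xxx), Y), 0)

    def total(self, a: int, Y: str) -> int:
        return self.n_total.get((a, Y), 0)

    def cumulative_correct_exact(self, Y: str, X: int) -> Fraction:
        """Exact cumulative correct-synthesis probability through position X.

        Product over ``a = 3..X`` of ``n(expected, a, Y) / n_total(a, Y)``
        in rational arithmetic; requires prefix conditioning (the product
        has no survival interpretation otherwise).
        """
        if self.conditioning != "prefix":
            raise ConfigError("exact cumulative product requires prefix conditioning")
        spec = self.specs[Y]
        prod = Fraction(1)
        for a in range(BARCODE_POSITION, X + 1):
            exp = expected_triplet(spec, a)
            if exp is None:
                raise ConfigError(f"template {Y} gives no instruction at position {a}")
            denom = self.total(a, Y)
            if denom == 0:
                raise ConfigError(f"no counts at position {a} for template {Y}")
            prod *= Fraction(self.n(a, exp, Y), denom)
        return prod


def count_conditional(
    decoded: Iterable[DecodedRead],
    specs: Mapping[str, TemplateSpec],
    barcode_map: Mapping[Triplet, str],
    positions: Sequence[int] = DEFAULT_POSITIONS,
    alphabet: TripletAlphabet = DEFAULT_ALPHABET,
    conditioning: str = "prefix",
) -> CountMatrix:
    """Count observed triplets per (position, template) with prefix conditioning.

    ``conditioning="prefix"`` (default) admits a read at position ``a`` only
    if its triplets at 1..a-1 all match the template's expectation (the
    template's own barcodes at barcode positions); ``"unconditional"``
    admits any classified read long enough, for sensitivity analysis.
    Reads whose adapter fell off the triplet frame are excluded entirely
    (their positions are ambiguous).  Classified reads shorter than a
    position simply do not contribute there.
    """
    if conditioning not in ("prefix", "unconditional"):
        raise ConfigError(f"conditioning must be prefix|unconditional, got {conditioning!r}")
    positions = tuple(positions)
    if positions and min(positions) < BARCODE_POSITION:
        raise ConfigError(f"positions start at the barcode position ({BARCODE_POSITION})")
    barcode_map = {Triplet(k): v for k, v in barcode_map.items()}
    for Y in set(barcode_map.values()):
        if Y not in specs:
            raise ConfigError(f"no TemplateSpec for classified template {Y!r}")

    counts: dict[tuple[int, Triplet, str], int] = {}
    n_total: dict[tuple[int, str], int] = {}
    other: dict[tuple[int, str], int] = {}
    n_classified: dict[str, int] = {Y: 0 for Y in set(barcode_map.values())}
    n_unclassified = 0
    pos_set = set(positions)
    max_pos = max(positions, default=0)

    for read in decoded:
        if read.adapter_found and not read.frame_ok:
            continue
        Y = classify_template(read, barcode_map)
        if Y is None:
            n_unclassified += 1
            continue
        n_classified[Y] += 1
        spec = specs[Y]
        prefix_ok = True
        for a in range(1, min(read.k, max_pos) + 1):
            obs = read.triplets[a - 1]
            exp = expected_triplet(spec, a)
            if a in pos_set and (conditioning == "unconditional" or prefix_ok):
                if obs in alphabet:
                    counts[(a, obs, Y)] = counts.get((a, obs, Y), 0) + 1
                    n_total[(a, Y)] = n_total.get((a, Y), 0) + 1
                else:
                    other[(a, Y)] = other.get((a, Y), 0) + 1
            if exp is None or obs != exp:
                prefix_ok = False
                if conditioning == "prefix":
                    break  # nothing past the first mismatch can be counted

    return CountMatrix(
        counts=counts,
        n_total=n_total,
        other=other,
        n_classified=n_classified,
        positions=positions,
        templates=tuple(sorted(n_classified)),
        alphabet=alphabet,
        conditioning=conditioning,
        specs=dict(specs),
        n_unclassified=n_unclassified,
    )


@dataclass
class FidelityMatrix:
    """Fidelity percentages ``F(a, xxx, Y)`` with per-cell n and masking."""

    F: dict[tuple[int, Triplet, str], float]
    n: dict[tuple[int, str], int]
    masked: dict[tuple[int, str], bool]
    positions: tuple[int, ...]
    templates: tuple[str, ...]
    alphabet: TripletAlphabet
    specs: Mapping[str, TemplateSpec] = field(default_factory=dict)
    mask_threshold: int = MASK_THRESHOLD

    def value(self, a: int, xxx: Triplet, Y: str) -> float:
        """F(a, xxx, Y) in percent; NaN when no reads were counted there."""
        if self.n.get((a, Y), 0) == 0:
            return math.nan
        return self.F.get((a, Triplet(xxx), Y), 0.0)

    def is_masked(self, a: int, Y: str) -> bool:
        return self.masked.get((a, Y), True)

    def to_frame(self, Y: str) -> pd.DataFrame:
        """Matrix for one template: rows = alphabet triplets (+ n and mask
        rows), columns = 1-based triplet positions."""
        data = {
            a: [self.value(a, t, Y) for t in self.alphabet] for a in self.positions
        }
        frame = pd.DataFrame(data, index=list(self.alphabet))
        frame.loc["n"] = [self.n.get((a, Y), 0) for a in self.positions]
        frame.loc["masked"] = [int(self.is_masked(a, Y)) for a in self.positions]
        frame.index.name = "triplet"
        return frame


def fidelity(counts: CountMatrix, mask_threshold: int = MASK_THRESHOLD) -> FidelityMatrix:
    """Turn raw counts into fidelity percentages with low-n masking."""
    F: dict[tuple[int, Triplet, str], float] = {}
    masked: dict[tuple[int, str], bool] = {}
    for Y in counts.templates:
        for a in counts.positions:
            total = counts.total(a, Y)
            masked[(a, Y)] = total <= mask_threshold
            if total == 0:
                continue
            for t in counts.alphabet:
                n = counts.n(a, t, Y)
                if n:
                    F[(a, t, Y)] = 100.0 * n / total
    return FidelityMatrix(
        F=F,
        n=dict(counts.n_total),
        masked=masked,
        positions=counts.positions,
        templates=counts.templates,
        alphabet=counts.alphabet,
        specs=counts.specs,
        mask_threshold=mask_threshold,
    )


def cumulative_correct(
    fm: FidelityMatrix, Y: str, X: int, spec: Optional[TemplateSpec] = None
) -> tuple[float, bool]:
    """Probability of fully templated synthesis from position 3 through X.

    Product of the correct-triplet fidelities over positions 3..X (the
    position-3 factor is 1 by construction of the classification).  Returns
    ``(probability, reliable)`` where ``reliable`` is False when any factor
    came from a masked (low-n) cell.
    """
    spec = spec if spec is not None else fm.specs[Y]
    prob = 1.0
    reliable = True
    for a in range(BARCODE_POSITION, X + 1):
        exp = expected_triplet(spec, a)
        if exp is None:
            raise ConfigError(f"template {Y} gives no instruction at position {a}")
        if fm.is_masked(a, Y):
            reliable = False
        v = fm.value(a, exp, Y)
        if math.isnan(v):
            return math.nan, False
        prob *= v / 100.0
    return prob, reliable


def fold_difference(p_circular: float, p_linear: float) -> float:
    """Circular/linear ratio of cumulative synthesis probabilities.

    A zero or undefined linear probability yields inf/NaN (reported, not
    raised: the comparison is still meaningful as a sentinel).
    """
    if math.isnan(p_circular) or math.isnan(p_linear):
        return math.nan
    if p_linear == 0:
        return math.inf if p_circular > 0 else math.nan
    return p_circular / p_linear
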