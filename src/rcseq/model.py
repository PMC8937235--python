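"""Domain types and geometry for triplet-based rolling circle synthesis (RCS).

A triplet polymerase ribozyme extends an RNA primer on a small circular
(or linear) RNA template in steps of three nucleotides ("triplets").
Everything downstream of the wet lab — read decoding, fidelity statistics,
concatemer spectra — is phrased in terms of *triplet positions*: 1-based
indices counted from the first extension triplet after the primer.  On a
circular template the expected triplet repeats with the circle's period;
on a linear template there is no instruction beyond the template end and
any further incorporation is non-templated (terminal-transferase regime).

Sequences are held in their sequenced cDNA representation (DNA alphabet);
RNA input is normalized one-way with U→T at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "Triplet",
    "TripletAlphabet",
    "TemplateSpec",
    "ProductSpec",
    "DEFAULT_ALPHABET",
    "GeometryError",
    "ConfigError",
    "normalize_seq",
    "expected_triplet",
    "full_circle_triplets",
    "product_length_nt",
    "circle_coverage",
]


class GeometryError(ValueError):
    """Circle/primer/product arithmetic received inconsistent lengths."""


class ConfigError(ValueError):
    """A template, product, or simulation specification violates its invariants."""


_DNA = frozenset("ACGT")


def normalize_seq(seq: str) -> str:
    """Uppercase a sequence and convert RNA to its cDNA representation (U→T).

    The conversion is one-way by design: all counting downstream is done on
    the DNA alphabet in which reads are delivered.
    """
    return seq.upper().replace("U", "T")


class Triplet(str):
    """A single 3-nt incorporation unit, stored as uppercase DNA.

    Accepts RNA input (``"GAA"`` and ``"gaa"`` and ``"GAU"`` → ``"GAT"``).
    Being a ``str`` subclass, triplets compare and hash like plain strings.
    """

    __slots__ = ()

    def __new__(cls, seq: str) -> "Triplet":
        s = normalize_seq(str(seq))
        if len(s) != 3:
            raise ConfigError(f"triplet must be exactly 3 nt, got {seq!r}")
        if set(s) - _DNA:
            raise ConfigError(f"triplet must be over A/C/G/T(U), got {seq!r}")
        return str.__new__(cls, s)


class TripletAlphabet:
    """Ordered set of triplets a polymerization experiment can draw from."""

    def __init__(self, members: Iterable[str]):
        mem = tuple(Triplet(m) for m in members)
        if len(set(mem)) != len(mem):
            raise ConfigError("alphabet members must be unique")
        self._members = mem
        self._set = frozenset(mem)

    @property
    def members(self) -> tuple[Triplet, ...]:
        return self._members

    def __contains__(self, item: object) -> bool:
        return item in self._set

    def __iter__(self) -> Iterator[Triplet]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TripletAlphabet) and other._members == self._members

    def __hash__(self) -> int:
        return hash(self._members)

    def __repr__(self) -> str:
        return f"TripletAlphabet({list(self._members)!r})"


#: The 14 triplet substrates offered in the barcoded one-pot experiments.
DEFAULT_ALPHABET = TripletAlphabet(
    [
        "CTG", "ATA", "CCA", "CCC", "AAA", "CAC", "GGG",
        "TTA", "TCC", "GGC", "ATC", "GAT", "CGC", "GAA",
    ]
)


@dataclass(frozen=True)
class TemplateSpec:
    """Expected product sequence of one template, in triplet coordinates.

    ``expected`` lists the expected extension triplet at positions ``1..P``.
    For a circular template ``P`` equals ``circle_len_nt / 3`` and positions
    wrap with that period; because the primer anneals to part of the circle,
    the last ``len(primer) / 3`` entries of one period are the primer's own
    triplets (beyond-full-length synthesis re-copies the primer site).  For
    a linear template ``expected`` covers the templated extension only and
    positions past its end have no instruction.

    ``barcode_positions`` records the positions at which this template
    carries an identifying triplet (its barcode); entries must agree with
    ``expected``.

    ``full_circle_override`` exists for circles whose length is not a
    multiple of 3 (the experimental series includes such sizes); it states
    the number of incorporations to full length explicitly instead of
    silently rounding, and such specs carry no ``expected`` list.
    """

    name: str
    topology: str  # "circular" | "linear"
    primer_seq: str
    expected: tuple[Triplet, ...] = ()
    circle_len_nt: Optional[int] = None
    barcode_positions: Mapping[int, Triplet] = field(default_factory=dict)
    full_circle_override: Optional[int] = None
    alphabet: TripletAlphabet = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ConfigError(f"topology must be circular|linear, got {self.topology!r}")
        object.__setattr__(self, "primer_seq", normalize_seq(self.primer_seq))
        object.__setattr__(self, "expected", tuple(Triplet(t) for t in self.expected))
        object.__setattr__(
            self,
            "barcode_positions",
            {int(p): Triplet(t) for p, t in dict(self.barcode_positions).items()},
        )
        if len(self.primer_seq) % 3 != 0:
            raise ConfigError(
                f"primer length must be a multiple of 3 "
                f"(primer occupies whole triplet slots), got {len(self.primer_seq)} nt"
            )
        if set(self.primer_seq) - _DNA:
            raise ConfigError(f"primer must be over A/C/G/T(U): {self.primer_seq!r}")
        if self.topology == "circular":
            if self.circle_len_nt is None:
                raise ConfigError(f"circular template {self.name!r} needs circle_len_nt")
            if self.circle_len_nt % 3 != 0:
                if self.full_circle_override is None:
                    raise ConfigError(
                        f"circle_len_nt={self.circle_len_nt} is not a multiple of 3; "
                        "provide full_circle_override for off-frame circles"
                    )
            elif self.expected:
                period = self.circle_len_nt // 3
                if len(self.expected) != period:
                    raise ConfigError(
                        f"expected list of circular template {self.name!r} must have "
                        f"one entry per triplet slot of the circle "
                        f"({period}), got {len(self.expected)}"
                    )
                ptrips = self.primer_triplets
                if self.expected[-len(ptrips):] != ptrips:
                    raise ConfigError(
                        f"last {len(ptrips)} expected triplets of circular template "
                        f"{self.name!r} must equal the primer's own triplets"
                    )
        for t in self.expected:
            if t not in self.alphabet:
                raise ConfigError(
                    f"expected triplet {t} of template {self.name!r} is outside the alphabet"
                )
        for pos, bc in self.barcode_positions.items():
            if pos < 1:
                raise ConfigError(f"barcode position must be ≥ 1, got {pos}")
            if bc not in self.alphabet:
                raise ConfigError(f"barcode {bc} at position {pos} is outside the alphabet")
            if self.expected:
                exp = expected_triplet(self, pos)
                if exp is not None and exp != bc:
                    raise ConfigError(
                        f"barcode {bc} at position {pos} of {self.name!r} disagrees "
                        f"with expected triplet {exp}"
                    )

    # -- derived geometry ------------------------------------------------

    @property
    def primer_len_nt(self) -> int:
        return len(self.primer_seq)

    @property
    def primer_triplets(self) -> tuple[Triplet, ...]:
        p = self.primer_seq
        return tuple(Triplet(p[i : i + 3]) for i in range(0, len(p), 3))

    @property
    def period(self) -> int:
        """Number of triplet positions before the expectation repeats (circular)
        or runs out (linear)."""
        return len(self.expected)

    @property
    def full_circle(self) -> int:
        """Number of triplet incorporations completing one full circle."""
        if self.topology != "circular":
            raise GeometryError(f"template {self.name!r} is linear; no full-circle count")
        if self.full_circle_override is not None:
            return self.full_circle_override
        assert self.circle_len_nt is not None
        return full_circle_triplets(self.circle_len_nt, self.primer_len_nt)


@dataclass(frozen=True)
class ProductSpec:
    """One of the distinct products of a multiply-primed (branched) circle.

    A branched RCS template carries more than one primer site, so the same
    circle yields products whose triplet expectations are phase-shifted
    copies of each other.  Each product is described by its own circular
    ``TemplateSpec`` (same circle, different phase) under a product name.
    """

    name: str
    template: TemplateSpec

    @property
    def topology(self) -> str:
        return self.template.topology

    @property
    def primer_seq(self) -> str:
        return self.template.primer_seq

    @property
    def expected(self) -> tuple[Triplet, ...]:
        return self.template.expected

    @property
    def period(self) -> int:
        return self.template.period

    @property
    def alphabet(self) -> TripletAlphabet:
        return self.template.alphabet

    @property
    def circle_len_nt(self) -> Optional[int]:
        return self.template.circle_len_nt

    @property
    def primer_len_nt(self) -> int:
        return self.template.primer_len_nt


SpecLike = Union[TemplateSpec, ProductSpec]


def expected_triplet(spec: SpecLike, position: int) -> Optional[Triplet]:
    """Expected triplet at a 1-based extension position, or None when the
    template gives no instruction (linear template, past its end).

    Circular templates wrap: position ``a + P`` expects the same triplet as
    position ``a``, where ``P`` is the circle's period in triplets.
    """
    if position < 1:
        raise ConfigError(f"triplet positions are 1-based, got {position}")
    P = spec.period
    if P == 0:
        raise ConfigError(f"template {spec.name!r} has no expected triplet list")
    if spec.topology == "circular":
        return spec.expected[(position - 1) % P]
    return spec.expected[position - 1] if position <= P else None


def full_circle_triplets(circle_len_nt: int, primer_len_nt: int) -> int:
    """Number of triplet incorporations that completes one circle.

    A primer of ``p`` nt annealed to a circle of ``C`` nt leaves
    ``(C - p) / 3`` triplet slots to fill before the product reaches the
    primer's own 5′ end (full length).
    """
    if circle_len_nt % 3 != 0 or primer_len_nt % 3 != 0:
        raise GeometryError(
            f"circle ({circle_len_nt} nt) and primer ({primer_len_nt} nt) must both "
            "be multiples of 3"
        )
    if primer_len_nt < 0 or circle_len_nt <= primer_len_nt:
        raise GeometryError(
            f"need circle_len_nt > primer_len_nt ≥ 0, got {circle_len_nt}, {primer_len_nt}"
        )
    return (circle_len_nt - primer_len_nt) // 3


def product_length_nt(primer_len_nt: int, k: int) -> int:
    """Total product length after ``k`` triplet incorporations on a primer."""
    if k < 0:
        raise GeometryError(f"incorporation count must be ≥ 0, got {k}")
    if primer_len_nt < 0:
        raise GeometryError(f"primer length must be ≥ 0, got {primer_len_nt}")
    return primer_len_nt + 3 * k


def circle_coverage(product_nt: int, circle_nt: int) -> float:
    """How many times the product spans the circle (product / circle length)."""
    if circle_nt <= 0:
        raise GeometryError(f"circle length must be positive, got {circle_nt}")
    return product_nt / circle_nt
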