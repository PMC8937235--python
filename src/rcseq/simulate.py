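"""Seeded generators of synthetic reads and gel lanes.

The read generator is the inverse of the decoding pipeline: it emits reads
of the form ``[sample barcode] + primer + triplets + [adapter + filler]``
where the triplet at extension position ``a`` is the template's expected
triplet with probability ``p_correct(a)`` and otherwise drawn from an
error distribution over the triplet alphabet; past the end of a linear
template (no instruction) triplets come from a terminal-transferase
distribution instead.  Each read carries a ground-truth record so that
decoding and fidelity estimation can be checked for exact round-trips and
parameter recovery.

The default fidelity profile mirrors the measured shape on circular
templates: a high plateau up to full length (one complete circle), a sharp
drop at the strand-invasion position just beyond it, and partial recovery
once invasion has succeeded.

The lane generator produces band intensities of a primer-extension lane
with a helically modulated per-junction efficiency,

    e_b = e0 * (1 - A * (1 + cos(2*pi*(3b + phase)/pitch)) / 2)

so that junctions facing the inside of the circle (cosine peak) are least
efficient; noiseless lanes conserve molecule counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .gel import A_FORM_PITCH_BP, LaneProfile
from .io import Read
from .model import (
    ConfigError,
    TemplateSpec,
    Triplet,
    expected_triplet,
    normalize_seq,
)

__all__ = [
    "SimConfig",
    "LaneSimConfig",
    "ADAPTER_PREFIX",
    "ADAPTER_FILLER",
    "simulate_dataset",
    "simulate_lane",
    "fidelity_profile",
    "fixed_termination",
]

#: 3' adapter prefix appended to completed reads (as sequenced, cDNA sense).
ADAPTER_PREFIX = "GTCGAATAT"
#: Fixed filler after the adapter prefix, standing in for the remainder of
#: the ligated adapter/library sequence.
ADAPTER_FILLER = "AGATCGGAAGAGC"


def fidelity_profile(
    max_pos: int,
    plateau: float = 0.90,
    invasion_pos: Optional[int] = 10,
    invasion: float = 0.11,
    recovery: float = 0.50,
) -> dict[int, float]:
    """Per-position correct-incorporation probabilities with an invasion dip.

    Defaults follow the measured circular-template profile: ~90% correct up
    to full length (position 9 on a 36-nt circle), ~11% at the invasion
    position (full length + 1), partial recovery beyond.  Pass
    ``invasion_pos=None`` for a flat plateau.
    """
    out = {}
    for a in range(1, max_pos + 1):
        if invasion_pos is None or a < invasion_pos:
            out[a] = plateau
        elif a == invasion_pos:
            out[a] = invasion
        else:
            out[a] = recovery
    return out


def fixed_termination(k: int) -> dict[int, float]:
    """Degenerate termination distribution: every read incorporates ``k`` triplets."""
    return {k: 1.0}


def _as_distribution(d: Mapping, what: str) -> tuple[list, np.ndarray]:
    keys = list(d.keys())
    probs = np.asarray([d[k] for k in keys], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ConfigError(f"{what} must be a probability distribution summing to 1")
    return keys, probs / probs.sum()


@dataclass
class SimConfig:
    """Generative parameters for one synthetic read set.

    ``p_correct`` must cover every templated position reachable under the
    termination distribution.  ``error_model`` defaults to uniform over the
    alphabet excluding the expected triplet; ``tt_model`` (non-templated
    appending past a linear template's end) defaults to uniform over the
    whole alphabet.
    """

    seed: int
    n_reads: int
    template: TemplateSpec
    p_correct: Mapping[int, float]
    termination: Mapping[int, float]
    error_model: Optional[Mapping[Triplet, float]] = None
    tt_model: Optional[Mapping[Triplet, float]] = None
    p_adapter: float = 1.0
    p_primer_present: float = 1.0
    sample_barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be ≥ 0")
        for name, p in (("p_adapter", self.p_adapter), ("p_primer_present", self.p_primer_present)):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for a, p in self.p_correct.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"p_correct[{a}]={p} outside [0, 1]")
        ks, _ = _as_distribution(self.termination, "termination")
        if any(k < 0 for k in ks):
            raise ConfigError("termination support must be ≥ 0")
        max_k = max(ks, default=0)
        for a in range(1, max_k + 1):
            if expected_triplet(self.template, a) is not None and a not in self.p_correct:
                raise ConfigError(
                    f"p_correct missing for reachable templated position {a} "
                    f"(termination reaches k={max_k})"
                )
        if self.sample_barcode is not None:
            self.sample_barcode = normalize_seq(self.sample_barcode)


def simulate_dataset(config: SimConfig) -> tuple[list[Read], pd.DataFrame]:
    """Generate reads and their ground-truth table, reproducibly from the seed.

    Per-read randomness comes from a substream derived from (seed, read
    index), so the output is byte-identical across runs and independent of
    chunking.  The truth table has one row per read with the template name,
    the drawn triplet count ``k``, the triplets themselves, per-position
    correctness flags ('1' templated-correct, '0' templated-error, 'T'
    non-templated), and adapter/primer presence flags.
    """
    tmpl = config.template
    alphabet = tmpl.alphabet
    term_keys, term_probs = _as_distribution(config.termination, "termination")
    if config.tt_model is not None:
        tt_keys, tt_probs = _as_distribution(
            {Triplet(k): v for k, v in config.tt_model.items()}, "tt_model"
        )
    else:
        tt_keys, tt_probs = list(alphabet), np.full(len(alphabet), 1 / len(alphabet))
    err_fixed = None
    if config.error_model is not None:
        err_fixed = _as_distribution(
            {Triplet(k): v for k, v in config.error_model.items()}, "error_model"
        )

    reads: list[Read] = []
    truth_rows = []
    for i in range(config.n_reads):
        rng = np.random.default_rng((config.seed, i))
        k = term_keys[rng.choice(len(term_keys), p=term_probs)]
        triplets: list[Triplet] = []
        flags: list[str] = []
        for a in range(1, k + 1):
            exp = expected_triplet(tmpl, a)
            if exp is None:
                t = tt_keys[rng.choice(len(tt_keys), p=tt_probs)]
                triplets.append(t)
                flags.append("T")
                continue
            if rng.random() < config.p_correct[a]:
                triplets.append(exp)
                flags.append("1")
            else:
                if err_fixed is not None:
                    ek, ep = err_fixed
                    t = ek[rng.choice(len(ek), p=ep)]
                else:
                    others = [t for t in alphabet if t != exp]
                    t = others[rng.integers(len(others))]
                triplets.append(t)
                flags.append("0")
        primer_present = rng.random() < config.p_primer_present
        adapter_present = rng.random() < config.p_adapter
        seq = (
            (config.sample_barcode or "")
            + (tmpl.primer_seq if primer_present else "")
            + "".join(triplets)
            + ((ADAPTER_PREFIX + ADAPTER_FILLER) if adapter_present else "")
        )
        read_id = f"sim{i:07d}"
        reads.append(Read(read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "template": tmpl.name,
                "k": k,
                "triplets": ",".join(triplets),
                "correct_flags": "".join(flags),
                "primer_present": int(primer_present),
                "adapter_present": int(adapter_present),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "template", "k", "triplets",
            "correct_flags", "primer_present", "adapter_present",
        ],
    )
    return reads, truth


@dataclass
class LaneSimConfig:
    """Parameters of one simulated primer-extension lane.

    ``pitch_bp`` defaults to the A-form dsRNA helical pitch (11.3 bp/turn);
    ``modulation_amplitude`` scales how strongly inside-facing junctions
    are disfavoured; ``noise_sd`` is the sigma of multiplicative log-normal
    band noise (0 = noiseless, conserving molecules exactly).
    """

    n_junctions: int
    e0: float = 0.8
    modulation_amplitude: float = 0.0
    pitch_bp: float = A_FORM_PITCH_BP
    phase_offset_bp: float = 0.0
    n_molecules: float = 1e6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_junctions < 1:
            raise ConfigError("n_junctions must be ≥ 1")
        if not 0 <= self.e0 <= 1:
            raise ConfigError("e0 must be in [0, 1]")
        if not 0 <= self.modulation_amplitude <= 1:
            raise ConfigError("modulation_amplitude must be in [0, 1]")
        if self.pitch_bp <= 2:
            raise ConfigError("pitch_bp must exceed 2 bp")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be ≥ 0")


def lane_efficiencies(config: LaneSimConfig) -> np.ndarray:
    """The programmed per-junction efficiencies ``e_1..e_n``."""
    b = np.arange(1, config.n_junctions + 1)
    theta = 2 * np.pi * (3 * b + config.phase_offset_bp) / config.pitch_bp
    return config.e0 * (1 - config.modulation_amplitude * (1 + np.cos(theta)) / 2)


def simulate_lane(config: LaneSimConfig) -> LaneProfile:
    """Band intensities of a lane with the configured junction efficiencies.

    ``I_b = N * prod(e_1..e_b) * (1 - e_(b+1))`` for ``b < n`` and
    ``I_n = N * prod(e_1..e_n)``; the intensities of a noiseless lane sum
    exactly to ``n_molecules``.
    """
    e = lane_efficiencies(config)
    surv = np.concatenate([[1.0], np.cumprod(e)])  # survivors past junction b, b=0..n
    I = np.empty(config.n_junctions + 1)
    I[:-1] = config.n_molecules * surv[:-1] * (1 - e)
    I[-1] = config.n_molecules * surv[-1]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        I = I * rng.lognormal(mean=0.0, sigma=config.noise_sd, size=I.size)
    return LaneProfile(
        I,
        metadata={
            "e0": config.e0,
            "modulation_amplitude": config.modulation_amplitude,
            "pitch_bp": config.pitch_bp,
            "phase_offset_bp": config.phase_offset_bp,
        },
    )
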