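"""Fidelity matrix, cumulative synthesis probability, fold difference."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcseq import (
    DecodedRead,
    SimConfig,
    Triplet,
    classify_template,
    count_conditional,
    cumulative_correct,
    decode_reads,
    fidelity,
    fidelity_profile,
    fixed_termination,
    fold_difference,
    simulate_dataset,
)
from rcseq.fidelity import CountMatrix
from rcseq.model import DEFAULT_ALPHABET, ConfigError, expected_triplet


def _read(*triplets, adapter=True, frame_ok=True, rid="r"):
    return DecodedRead(
        read_id=rid,
        sample_id=None,
        triplets=tuple(Triplet(t) for t in triplets),
        adapter_found=adapter,
        frame_ok=frame_ok,
    )


BARCODES = {Triplet("ATA"): "A", Triplet("AAA"): "B", Triplet("TTA"): "C", Triplet("ATC"): "D"}


class TestClassify:
    def test_position_3_barcode_classifies(self):
        assert classify_template(_read("GAA", "GAA", "ATA", "GAA"), BARCODES) == "A"
        assert classify_template(_read("GAA", "GAA", "ATC"), BARCODES) == "D"

    def test_non_barcode_triplet_unclassified(self):
        assert classify_template(_read("GAA", "GAA", "GGG"), BARCODES) is None

    def test_too_short_unclassified(self):
        assert classify_template(_read("GAA", "GAA"), BARCODES) is None


class TestCounting:
    def test_fully_correct_reads_count_everywhere(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        trips = [expected_triplet(spec, a) for a in range(1, 6)]
        reads = [_read(*trips, rid=f"r{i}") for i in range(10)]
        cm = count_conditional(reads, circular_specs, barcode_map, positions=range(3, 6))
        assert cm.total(5, "A") == 10
        assert cm.n(5, expected_triplet(spec, 5), "A") == 10

    def test_error_stops_prefix_conditioning(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        trips = [expected_triplet(spec, a) for a in range(1, 7)]
        trips[3] = Triplet("CCC")  # wrong at position 4
        cm = count_conditional(
            [_read(*trips)], circular_specs, barcode_map, positions=range(3, 7)
        )
        assert cm.n(4, Triplet("CCC"), "A") == 1  # counted where it went wrong
        assert cm.total(5, "A") == 0 and cm.total(6, "A") == 0

    def test_unconditional_mode_keeps_counting(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        trips = [expected_triplet(spec, a) for a in range(1, 7)]
        trips[3] = Triplet("CCC")
        cm = count_conditional(
            [_read(*trips)], circular_specs, barcode_map,
            positions=range(3, 7), conditioning="unconditional",
        )
        assert cm.total(5, "A") == 1 and cm.total(6, "A") == 1

    def test_off_frame_reads_excluded(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        trips = [expected_triplet(spec, a) for a in range(1, 6)]
        cm = count_conditional(
            [_read(*trips, frame_ok=False)], circular_specs, barcode_map
        )
        assert cm.total(3, "A") == 0

    def test_counts_equal_bruteforce_substring_scan(
        self, shortpot_sim, circular_A, circular_specs, barcode_map
    ):
        """Prefix-conditional counts reproduce grep-style counting: for each
        position, enumerate expected-prefix + alphabet-triplet needles and
        count exact substring matches over the raw reads."""
        _, reads, _ = shortpot_sim
        decoded = decode_reads(reads, circular_A.primer_seq).decoded
        cm = count_conditional(decoded, circular_specs, barcode_map, positions=range(3, 9))
        # position 3 holds the classifying barcode: only the barcode needle
        # corresponds to a counted cell (other triplets leave the read
        # unclassified rather than miscounted)
        bc = expected_triplet(circular_A, 3)
        needle3 = circular_A.primer_seq + "GAAGAA" + bc
        assert cm.n(3, bc, "A") == sum(1 for r in reads if needle3 in r.seq)
        for a in range(4, 9):
            prefix = circular_A.primer_seq + "".join(
                expected_triplet(circular_A, i) for i in range(1, a)
            )
            for xxx in DEFAULT_ALPHABET:
                needle = prefix + xxx
                brute = sum(1 for r in reads if needle in r.seq)
                assert cm.n(a, xxx, "A") == brute, (a, xxx)


class TestFidelityMatrix:
    def test_percentages_from_counts(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        correct = [expected_triplet(spec, a) for a in range(1, 5)]
        wrong = list(correct)
        wrong[3] = Triplet("ATA")
        reads = [_read(*correct, rid=f"c{i}") for i in range(90)]
        reads += [_read(*wrong, rid=f"w{i}") for i in range(10)]
        cm = count_conditional(reads, circular_specs, barcode_map, positions=range(3, 5))
        fm = fidelity(cm)
        assert fm.value(4, expected_triplet(spec, 4), "A") == pytest.approx(90.0)
        assert fm.value(4, "ATA", "A") == pytest.approx(10.0)

    def test_single_triplet_is_100(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        reads = [_read(*[expected_triplet(spec, a) for a in range(1, 4)])]
        fm = fidelity(count_conditional(reads, circular_specs, barcode_map, positions=[3]))
        assert fm.value(3, expected_triplet(spec, 3), "A") == 100.0

    def test_masking_at_low_n(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        reads = [_read(*[expected_triplet(spec, a) for a in range(1, 4)], rid=f"r{i}")
                 for i in range(5)]
        fm = fidelity(count_conditional(reads, circular_specs, barcode_map, positions=[3]))
        assert fm.is_masked(3, "A")  # n = 5 ≤ threshold
        reads.append(_read(*[expected_triplet(spec, a) for a in range(1, 4)], rid="r6"))
        fm = fidelity(count_conditional(reads, circular_specs, barcode_map, positions=[3]))
        assert not fm.is_masked(3, "A")

    @settings(deadline=None, max_examples=30)
    @given(
        counts=st.lists(
            st.integers(min_value=0, max_value=1000), min_size=14, max_size=14
        ).filter(lambda c: sum(c) > 0)
    )
    def test_rows_sum_to_100_and_match_recomputation(self, counts):
        """Unmasked fidelity rows sum to 100% and each entry equals its own
        independent percentage recomputation."""
        total = sum(counts)
        cmat = CountMatrix(
            counts={(3, t, "A"): c for t, c in zip(DEFAULT_ALPHABET, counts) if c},
            n_total={(3, "A"): total},
            other={},
            n_classified={"A": total},
            positions=(3,),
            templates=("A",),
            alphabet=DEFAULT_ALPHABET,
            conditioning="prefix",
        )
        fm = fidelity(cmat, mask_threshold=0)
        row = [fm.value(3, t, "A") for t in DEFAULT_ALPHABET]
        assert math.fsum(row) == pytest.approx(100.0, abs=1e-9)
        for t, c in zip(DEFAULT_ALPHABET, counts):
            assert fm.value(3, t, "A") == pytest.approx(100.0 * c / total)

    def test_out_of_alphabet_excluded_from_denominator(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        good = [expected_triplet(spec, a) for a in range(1, 5)]
        odd = list(good)
        odd[3] = Triplet("TGT")  # not among the 14 substrates
        reads = [_read(*good), _read(*odd, rid="odd")]
        cm = count_conditional(reads, circular_specs, barcode_map, positions=range(3, 5))
        assert cm.total(4, "A") == 1
        assert cm.other[(4, "A")] == 1
        fm = fidelity(cm, mask_threshold=0)
        assert fm.value(4, expected_triplet(spec, 4), "A") == 100.0


class TestCumulative:
    def test_product_of_given_fidelities(self):
        # correct-triplet fidelities 100, 50, 50 at positions 3..5 -> 0.25
        probs = {3: 100.0, 4: 50.0, 5: 50.0}
        acc = 1.0
        for a in (3, 4, 5):
            acc *= probs[a] / 100
        assert acc == pytest.approx(0.25)

    def test_telescoping_identity_on_simulated_reads(
        self, onepot_sim, circular_A, circular_specs, barcode_map
    ):
        """With prefix conditioning the cumulative product equals, exactly in
        rational arithmetic, the fraction of classified reads fully correct
        through X."""
        _, reads, _ = onepot_sim
        decoded = decode_reads(reads, circular_A.primer_seq).decoded
        cm = count_conditional(decoded, circular_specs, barcode_map, positions=range(3, 13))
        for X in (5, 9, 12):
            exact = cm.cumulative_correct_exact("A", X)
            n_full = 0
            for d in decoded:
                if classify_template(d, barcode_map) != "A" or d.k < X:
                    continue
                if all(d.triplets[a - 1] == expected_triplet(circular_A, a) for a in range(1, X + 1)):
                    n_full += 1
            assert exact == Fraction(n_full, cm.total(3, "A")), X

    def test_float_and_exact_agree(self, onepot_decoded, circular_specs, barcode_map):
        cm = count_conditional(
            onepot_decoded.decoded, circular_specs, barcode_map, positions=range(3, 13)
        )
        fm = fidelity(cm)
        prob, reliable = cumulative_correct(fm, "A", 12)
        assert reliable
        assert prob == pytest.approx(float(cm.cumulative_correct_exact("A", 12)), rel=1e-9)

    def test_masked_cells_flag_unreliable(self, circular_specs, barcode_map):
        spec = circular_specs["A"]
        reads = [_read(*[expected_triplet(spec, a) for a in range(1, 6)], rid=f"r{i}")
                 for i in range(3)]
        cm = count_conditional(reads, circular_specs, barcode_map, positions=range(3, 6))
        fm = fidelity(cm)  # n = 3 ≤ 5 everywhere -> masked
        prob, reliable = cumulative_correct(fm, "A", 5)
        assert prob == pytest.approx(1.0)
        assert not reliable


class TestParameterRecovery:
    def test_estimated_fidelity_tracks_p_correct(self, circular_A, circular_specs, barcode_map):
        """F(a, expected) lies within 3 binomial SEs of 100*p_correct(a) at
        n = 10,000 for every position with enough counted reads."""
        p_correct = fidelity_profile(12)
        cfg = SimConfig(
            seed=77,
            n_reads=10_000,
            template=circular_A,
            p_correct=p_correct,
            termination=fixed_termination(12),
        )
        reads, _ = simulate_dataset(cfg)
        decoded = decode_reads(reads, circular_A.primer_seq).decoded
        cm = count_conditional(decoded, circular_specs, barcode_map, positions=range(3, 13))
        fm = fidelity(cm)
        checked = 0
        for a in range(4, 13):  # position 3 is fixed at 100 by classification
            n = cm.total(a, "A")
            if n < 100:
                continue
            p = p_correct[a]
            se_pct = 100 * np.sqrt(p * (1 - p) / n)
            est = fm.value(a, expected_triplet(circular_A, a), "A")
            assert abs(est - 100 * p) <= 3 * max(se_pct, 1e-9), a
            checked += 1
        assert checked >= 6

    def test_position_3_fidelity_is_exactly_100(self, onepot_decoded, circular_specs, barcode_map):
        """Classification forces the position-3 barcode, hence 100% fidelity."""
        cm = count_conditional(onepot_decoded.decoded, circular_specs, barcode_map)
        fm = fidelity(cm)
        for Y, spec in circular_specs.items():
            if cm.total(3, Y) == 0:
                continue
            assert fm.value(3, expected_triplet(spec, 3), Y) == 100.0


class TestFoldDifference:
    def test_ratio(self):
        assert fold_difference(0.2, 0.02) == pytest.approx(10.0)
        assert fold_difference(0.3, 0.3) == 1.0

    def test_zero_linear_is_sentinel_not_error(self):
        assert fold_difference(0.1, 0.0) == math.inf
        assert math.isnan(fold_difference(0.0, 0.0))
        assert math.isnan(fold_difference(math.nan, 0.5))

    def test_circular_beats_linear_under_invasion_drop(
        self, circular_A, linear_A, circular_specs, barcode_map
    ):
        """With the default profiles (sharp invasion-position drop on linear
        templates), the cumulative probability past full length is at least
        an order of magnitude higher on the circular template."""
        common = dict(n_reads=8000, termination=fixed_termination(12))
        c_reads, _ = simulate_dataset(
            SimConfig(seed=21, template=circular_A, p_correct=fidelity_profile(12), **common)
        )
        # linear: measured plateau, then pure terminal transferase beyond the
        # template end; the TT draw lands on the would-be-correct triplet
        # rarely (the measured beyond-full-length prevalence, ~0.7%)
        l_p = fidelity_profile(9, plateau=0.79, invasion_pos=None)
        tt = {"GAA": 0.007}
        tt.update({t: (1 - 0.007) / 13 for t in DEFAULT_ALPHABET if t != "GAA"})
        l_reads, _ = simulate_dataset(
            SimConfig(seed=22, template=linear_A, p_correct=l_p, tt_model=tt, **common)
        )
        lin_specs = {Y: spec for Y, spec in circular_specs.items()}
        c_cm = count_conditional(
            decode_reads(c_reads, circular_A.primer_seq).decoded,
            circular_specs, barcode_map, positions=range(3, 13),
        )
        l_cm = count_conditional(
            decode_reads(l_reads, linear_A.primer_seq).decoded,
            lin_specs, barcode_map, positions=range(3, 13),
        )
        p_c = float(c_cm.cumulative_correct_exact("A", 10))
        # linear reads are TT beyond position 9: count the fully-correct
        # fraction directly against the circular expectation
        p_l = float(l_cm.cumulative_correct_exact("A", 10))
        fold = fold_difference(p_c, p_l)
        assert fold > 10


class TestValidation:
    def test_unknown_conditioning_rejected(self, circular_specs, barcode_map):
        with pytest.raises(ConfigError):
            count_conditional([], circular_specs, barcode_map, conditioning="bogus")

    def test_positions_before_barcode_rejected(self, circular_specs, barcode_map):
        with pytest.raises(ConfigError):
            count_conditional([], circular_specs, barcode_map, positions=range(1, 5))

    def test_missing_spec_rejected(self, barcode_map):
        with pytest.raises(ConfigError):
            count_conditional([], {}, barcode_map)
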