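"""Window scans and segment scores: arithmetic, determinism, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemscan.errors import ConfigError
from stemscan.folding import FoldConfig, ensemble_energies
from stemscan.scanning import (
    WindowSpec,
    calibrate_with_scrambles,
    null_energy_profile,
    scan,
    segment_score,
    window_centre,
)
from stemscan.sequences import SequenceRecord
from stemscan.shuffling import make_null_set
from stemscan.synthetic import HairpinSpec, SyntheticSpec, random_background


class TestSegmentScore:
    def test_score_vanishes_when_energy_equals_null_mean(self):
        assert segment_score(-8.0, [-7.0, -8.0, -9.0]).s == 0.0

    def test_toy_score_is_minus_two(self):
        score = segment_score(-10.0, [-7.0, -8.0, -9.0])
        assert score.null_mean == pytest.approx(-8.0)
        assert score.null_sd == pytest.approx(1.0)  # sample (n-1) sd
        assert score.s == pytest.approx(-2.0)

    def test_degenerate_null_flagged_not_infinite(self):
        score = segment_score(-3.0, [-5.0, -5.0, -5.0])
        assert score.s == 0.0 and score.degenerate

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            segment_score(-1.0, [])

    @settings(max_examples=60, derandomize=True)
    @given(
        e=st.floats(-50, 0),
        nulls=st.lists(st.floats(-50, 0), min_size=3, max_size=10, unique=True),
        shift=st.floats(-20, 20),
        scale=st.floats(0.1, 10),
    )
    def test_invariant_under_affine_rescaling_of_all_energies(self, e, nulls, shift, scale):
        base = segment_score(e, nulls)
        moved = segment_score(scale * e + shift, [scale * x + shift for x in nulls])
        if not base.degenerate:
            assert moved.s == pytest.approx(base.s, rel=1e-6, abs=1e-9)


class TestScan:
    def test_homopolymer_scan_is_flat_and_degenerate(self, thermo):
        rec = SequenceRecord("polyA", "A" * 120)
        profile = scan(rec, WindowSpec(sizes=(50,)), n_null=3, seed=0, config=thermo)
        assert len(profile) == 71
        for r in profile.results:
            assert r.e_mfe == 0.0 and r.g_ensemble == 0.0
            assert r.score_mfe.degenerate and r.score_ensemble.degenerate

    def test_windows_ordered_with_left_of_middle_centres(self):
        spec = WindowSpec(sizes=(30, 32))
        windows = list(spec.windows(1, 40))
        assert windows[0] == (30, 1) and windows[-1] == (32, 9)
        assert window_centre(1, 30) == 15
        assert window_centre(1, 31) == 16

    def test_scan_is_deterministic_bitwise(self, thermo):
        rng = np.random.default_rng(4)
        rec = SequenceRecord("r", "".join(rng.choice(list("ACGU"), size=80)))
        spec = WindowSpec(sizes=(40,))
        a = scan(rec, spec, n_null=5, seed=9, config=thermo)
        b = scan(rec, spec, n_null=5, seed=9, config=thermo)
        assert a == b

    def test_ensemble_below_mfe_across_whole_scan(self, thermo):
        rng = np.random.default_rng(5)
        rec = SequenceRecord("r", "".join(rng.choice(list("ACGU"), size=100)))
        profile = scan(rec, WindowSpec(sizes=(30, 50)), n_null=0, config=thermo)
        for r in profile.results:
            assert r.g_ensemble <= r.e_mfe + 1e-9
            assert r.g_per_nt == pytest.approx(r.g_ensemble / r.size)

    def test_all_sizes_longer_than_sequence_is_an_error(self, thermo):
        rec = SequenceRecord("short", "ACGUACGUAC")
        with pytest.raises(ConfigError):
            scan(rec, WindowSpec(sizes=(50,)), config=thermo)

    def test_matches_naive_reimplementation_exactly(self, thermo):
        # Naive loop: direct folding + null construction per window, no reuse.
        rng = np.random.default_rng(21)
        rec = SequenceRecord("r", "".join(rng.choice(list("ACGU"), size=120)))
        spec = WindowSpec(sizes=(30,))
        n_null, seed = 5, 3
        profile = scan(rec, spec, n_null=n_null, seed=seed, config=thermo)
        for result in profile.results:
            window = rec.residues[result.start - 1 : result.start - 1 + result.size]
            e_mfe, g_ens = ensemble_energies(window, thermo)
            assert (result.e_mfe, result.g_ensemble) == (e_mfe, g_ens)
            nulls = make_null_set(window, n=n_null, seed=seed, stream=(result.size, result.start))
            null_energies = [ensemble_energies(m, thermo) for m in nulls.members]
            s_mfe = segment_score(e_mfe, [x[0] for x in null_energies], "mfe")
            s_ens = segment_score(g_ens, [x[1] for x in null_energies], "ensemble")
            assert result.score_mfe == s_mfe
            assert result.score_ensemble == s_ens

    def test_planted_hairpin_drives_profile_minimum_to_the_locus(self, thermo):
        spec = SyntheticSpec(
            length=200,
            composition={"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3},
            hairpin=HairpinSpec(stem_length=12, loop_length=4, position=90),
            seed=17,
        )
        rec, truth = random_background(spec)
        profile = scan(rec, WindowSpec(sizes=(50,)), n_null=0, config=thermo)
        minimum = profile.minimum(50)
        lo, hi = truth["planted_interval"]
        assert lo - 5 <= minimum.centre <= hi + 5


class TestNullProfile:
    def test_null_profile_tracks_composition(self, thermo):
        # G/C-rich half folds more stably than the A/U-rich half even for
        # scrambles: composition alone drives the dashed-line profile down.
        rng = np.random.default_rng(30)
        gc_half = "".join(rng.choice(list("GC"), size=60))
        au_half = "".join(rng.choice(list("AU"), size=60))
        rec = SequenceRecord("halves", gc_half + au_half)
        series = null_energy_profile(rec, WindowSpec(sizes=(40,)), n_null=5, seed=2, config=thermo)
        centres = np.array([c for c, _ in series])
        values = np.array([v for _, v in series])
        assert values[centres <= 40].mean() < values[centres >= 80].mean()

    def test_requires_at_least_one_null(self, thermo):
        rec = SequenceRecord("r", "ACGU" * 20)
        with pytest.raises(ValueError):
            null_energy_profile(rec, WindowSpec(sizes=(30,)), n_null=0, config=thermo)


class TestCalibration:
    def test_native_minimum_lies_inside_scramble_support(self, thermo):
        # Exchangeability self-test: a dinucleotide-typical sequence's
        # extreme score should not escape the support of its scrambles'.
        rng = np.random.default_rng(40)
        rec = SequenceRecord("bg", "".join(rng.choice(list("ACGU"), size=70)))
        cal = calibrate_with_scrambles(
            rec, n_scrambles=8, window=30, n_null=8, seed=5, config=thermo
        )
        lo = min(cal.scramble_mins) - 3.0
        hi = max(cal.scramble_mins) + 3.0
        assert lo <= cal.native_min <= hi
        assert 0.0 <= cal.native_quantile <= 1.0

    def test_planted_element_sits_low_in_the_scramble_distribution(self, thermo):
        spec = SyntheticSpec(
            length=120,
            composition={"A": 0.35, "C": 0.15, "G": 0.15, "U": 0.35},
            hairpin=HairpinSpec(stem_length=12, loop_length=4, position=50),
            seed=8,
        )
        rec, _ = random_background(spec)
        cal = calibrate_with_scrambles(
            rec, n_scrambles=8, window=50, n_null=8, seed=5, config=thermo
        )
        assert cal.native_quantile <= 0.5

    def test_zero_scrambles_rejected(self, thermo):
        rec = SequenceRecord("r", "ACGU" * 20)
        with pytest.raises(ValueError):
            calibrate_with_scrambles(rec, n_scrambles=0, config=thermo)
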