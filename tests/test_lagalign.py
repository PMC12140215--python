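import numpy as np
import pandas as pd
import pytest

import entrainkit as ek
from entrainkit.circstats import PhaseBinning, wrap_phase
from entrainkit.cosinefit import EmptyBinError
from entrainkit.lagalign import (
    LagProfile,
    exp1_pipeline,
    extract_tacs_phase,
    half_cycle_summary,
    lag_binning,
    profile_entrainment_by_lag,
    realign_profile,
    second_level_fit,
    tacs_effect_zscores,
)


class TestExtractTacsPhase:
    def test_pure_tone_phase_convention_and_slope(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        phase = extract_tacs_phase(np.cos(2 * np.pi * 2 * t), fs)
        # phase ~0 at cosine peaks (away from filter edges)
        peaks = (np.arange(2, 18) * 0.5 * fs).astype(int)
        assert np.abs(wrap_phase(phase[peaks])).max() < 0.05
        # unwrapped slope ~ 2*pi*2 rad/s
        mid = slice(int(2 * fs), int(8 * fs))
        slope = np.polyfit(t[mid], np.unwrap(phase)[mid], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 2, rel=0.01)

    def test_noise_robustness(self):
        fs = 500.0
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 1 / fs)
        true_phase = wrap_phase(2 * np.pi * 2 * t)
        sig = np.cos(2 * np.pi * 2 * t) + 0.05 * rng.standard_normal(t.size)
        est = extract_tacs_phase(sig, fs)
        mid = slice(int(2 * fs), int(18 * fs))
        err = np.abs(wrap_phase(est[mid] - true_phase[mid]))
        assert np.mean(err) < 0.1

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_tacs_phase(np.ones(5000), 500.0)


class TestLagBinning:
    @pytest.mark.parametrize(
        "fm, tacs, expected",
        [(0.3, 0.3, 0.0), (0.0, np.pi / 2, -np.pi / 2), (-3.0, 3.0, 2 * np.pi - 6.0)],
    )
    def test_lag_examples(self, fm, tacs, expected):
        lag, _ = lag_binning(fm, tacs)
        assert lag == pytest.approx(wrap_phase(expected), abs=1e-12)

    def test_uniform_inputs_fill_bins(self):
        rng = np.random.default_rng(1)
        fm = rng.uniform(-np.pi, np.pi, 6000)
        tacs = rng.uniform(-np.pi, np.pi, 6000)
        _, idx = lag_binning(fm, tacs)
        counts = np.bincount(idx, minlength=6)
        assert counts.min() > 0.8 * counts.mean()


def make_lag_table(rng, n, amp_fn, base=0.5, pref=0.0):
    """Active-tACS trials with entrainment amplitude depending on lag bin."""
    fm_b = PhaseBinning(9)
    lag_b = PhaseBinning(6)
    fm = fm_b.bin_centers[rng.integers(0, 9, n)]
    lag = lag_b.bin_centers[rng.integers(0, 6, n)]
    p = base + amp_fn(lag) * np.cos(fm - pref)
    acc = (rng.random(n) < np.clip(p, 0.02, 0.98)).astype(int)
    return pd.DataFrame({
        "participant_id": 0, "session_id": 1, "condition": 1.0,
        "tacs_condition": "active", "gap_time": 5.0,
        "fm_phase": fm, "tacs_phase": wrap_phase(fm - lag), "tacs_lag": lag,
        "accuracy": acc,
    })


class TestProfile:
    def test_lag_independent_amplitude_gives_flat_profile(self):
        rng = np.random.default_rng(2)
        table = make_lag_table(rng, 60_000, lambda lag: 0.15 + 0 * lag)
        prof = profile_entrainment_by_lag(table)
        assert prof.entamp_per_lag.std() < 0.02
        np.testing.assert_allclose(prof.entamp_per_lag, 0.15, atol=0.03)

    def test_profile_peaks_at_generating_optimal_lag(self):
        rng = np.random.default_rng(3)
        lag_opt = PhaseBinning(6).bin_centers[2]
        table = make_lag_table(
            rng, 120_000, lambda lag: 0.12 * (1 + 0.5 * np.cos(lag - lag_opt))
        )
        prof = exp1_pipeline(table)
        assert prof.optimal_bin == 2
        assert np.abs(wrap_phase(prof.optimal_lag - lag_opt)) < 0.3
        assert prof.tacs_plus > prof.tacs_minus

    def test_empty_cell_raises_with_location(self):
        rng = np.random.default_rng(4)
        table = make_lag_table(rng, 2000, lambda lag: 0.1)
        b6 = PhaseBinning(6)
        drop = b6.assign(table["tacs_lag"].to_numpy()) == 3
        drop &= PhaseBinning(9).assign(table["fm_phase"].to_numpy()) == 5
        with pytest.raises(EmptyBinError, match=r"\(5, 3\)"):
            profile_entrainment_by_lag(table[~drop])


class TestSecondLevelAndRealign:
    def test_exact_recovery_from_cosine_profile(self):
        lag_b = PhaseBinning(6)
        prof = LagProfile(lag_b.bin_centers, 0.1 + 0.05 * np.cos(lag_b.bin_centers - 1.0))
        second_level_fit(prof)
        assert prof.optimal_lag == pytest.approx(1.0, abs=1e-10)
        # adding a constant leaves the optimal lag unchanged
        prof2 = LagProfile(lag_b.bin_centers, prof.entamp_per_lag + 0.2)
        second_level_fit(prof2)
        assert prof2.optimal_lag == pytest.approx(1.0, abs=1e-10)

    def test_flat_profile_flagged_degenerate(self):
        lag_b = PhaseBinning(6)
        prof = second_level_fit(LagProfile(lag_b.bin_centers, np.full(6, 0.1)))
        assert prof.second_level_fit.degenerate

    def test_realignment_rotation_and_exclusion(self):
        lag_b = PhaseBinning(6)
        values = np.array([0.1, 0.2, 0.5, 0.3, 0.15, 0.05])
        prof = LagProfile(lag_b.bin_centers, values)
        prof.optimal_lag = float(lag_b.bin_centers[2])  # exactly bin 2's center
        realign_profile(prof)
        assert prof.optimal_bin == 2
        np.testing.assert_allclose(prof.realigned_values, np.roll(values, -2))
        assert prof.excluded.sum() == 2
        assert prof.excluded[0] and prof.excluded[3]

    def test_realigning_aligned_profile_is_identity(self):
        lag_b = PhaseBinning(6)
        values = 0.1 + 0.05 * np.cos(lag_b.bin_centers)  # peak already at bin 0
        prof = second_level_fit(LagProfile(lag_b.bin_centers, values))
        realign_profile(prof)
        assert prof.optimal_bin == 0
        np.testing.assert_allclose(prof.realigned_values, values)

    def test_half_cycle_definition(self):
        lag_b = PhaseBinning(6)
        v = np.array([9.0, 1.0, 2.0, 9.0, 4.0, 5.0])  # 9s land on excluded bins
        prof = LagProfile(lag_b.bin_centers, v)
        prof.optimal_lag = 0.0
        realign_profile(prof)
        plus, minus = half_cycle_summary(prof)
        assert plus == pytest.approx((1.0 + 5.0) / 2)
        assert minus == pytest.approx((2.0 + 4.0) / 2)
        # constant retained values collapse to that constant
        prof2 = LagProfile(lag_b.bin_centers, np.array([9.0, 3.0, 3.0, 9.0, 3.0, 3.0]))
        prof2.optimal_lag = 0.0
        realign_profile(prof2)
        assert half_cycle_summary(prof2) == (3.0, 3.0)


class TestRotationInvariance:
    def test_rotating_tacs_phases_rotates_optimal_lag_only(self):
        rng = np.random.default_rng(5)
        lag_opt = PhaseBinning(6).bin_centers[1]
        table = make_lag_table(
            rng, 80_000, lambda lag: 0.12 * (1 + 0.5 * np.cos(lag - lag_opt))
        )
        prof = exp1_pipeline(table)
        delta = 2 * np.pi / 6  # one full bin, so bin structure is preserved
        rot = table.copy()
        rot["tacs_phase"] = wrap_phase(rot["tacs_phase"] + delta)
        rot["tacs_lag"] = wrap_phase(rot["fm_phase"] - rot["tacs_phase"])
        prof_rot = exp1_pipeline(rot)
        assert np.abs(
            wrap_phase(prof_rot.optimal_lag - (prof.optimal_lag - delta))
        ) < 1e-6
        assert prof_rot.tacs_plus == pytest.approx(prof.tacs_plus, abs=1e-12)
        assert prof_rot.tacs_minus == pytest.approx(prof.tacs_minus, abs=1e-12)


class TestTacsEffect:
    def test_modulated_generator_gives_positive_contrast_z(self):
        table, truth = ek.simulate_exp1(
            n_participants=1, seed=21, tacs_modulation=0.8,
            fm_amp={11.0: 0.15, 39.0: 0.2},
            config=ek.DesignConfig(
                experiment="exp1", n_participants=1, conditions=(11.0,),
                stimuli_per_block=64, seed=21,
            ),
        )
        eff = tacs_effect_zscores(table, n_perm=300, seed=1)
        assert eff.plus_minus_minus == pytest.approx(
            eff.plus_minus_sham - eff.minus_minus_sham, abs=1e-12
        )
        assert eff.z_plus_minus_minus > 1.0

    def test_surrogate_value_lies_inside_own_null(self):
        rng = np.random.default_rng(6)
        table = make_lag_table(rng, 5000, lambda lag: 0.1)
        sham = table.copy()
        sham["tacs_condition"] = "sham"
        both = pd.concat([table, sham.iloc[:1000]], ignore_index=True)
        eff = tacs_effect_zscores(both, n_perm=300, seed=2)
        # null generator: contrasts should not be extreme
        assert abs(eff.z_plus_minus_minus) < 3.5
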