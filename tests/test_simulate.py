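import numpy as np
import pandas as pd
import pytest

import entrainkit as ek
from entrainkit.circstats import PhaseBinning
from entrainkit.simulate import (
    BehavioralModelParams,
    DesignConfig,
    PackingError,
    classify_responses,
    gen_design,
    hit_probability,
    response_events,
    simulate_eeg_epochs,
    simulate_outcomes,
)


@pytest.fixture(scope="module")
def exp1_design():
    cfg = DesignConfig(experiment="exp1", n_participants=2, seed=5)
    return cfg, gen_design(cfg)


class TestGenDesign:
    def test_deterministic(self, exp1_design):
        cfg, table = exp1_design
        again = gen_design(cfg)
        pd.testing.assert_frame_equal(table, again)

    def test_fm_phases_are_bin_centers(self, exp1_design):
        cfg, table = exp1_design
        centers = PhaseBinning(cfg.n_fm_phase_bins).bin_centers
        d = np.abs(table["fm_phase"].to_numpy()[:, None] - centers[None, :]).min(axis=1)
        assert d.max() < 1e-9

    def test_bin_occupancy_near_uniform(self, exp1_design):
        cfg, table = exp1_design
        b = PhaseBinning(cfg.n_fm_phase_bins)
        for _, sub in table.groupby(["participant_id", "condition"]):
            counts = np.bincount(b.assign(sub["fm_phase"].to_numpy()), minlength=9)
            assert counts.min() > 0.6 * counts.mean()

    def test_gap_spacing_and_edges(self, exp1_design):
        cfg, table = exp1_design
        for _, sub in table.groupby(
            ["participant_id", "condition", "block", "stimulus"]
        ):
            t = np.sort(sub["gap_time"].to_numpy())
            assert t.min() > cfg.edge_margin
            assert t.max() < cfg.stimulus_duration - cfg.edge_margin
            if t.size > 1:
                assert np.diff(t).min() >= cfg.min_gap_spacing - 1e-9

    def test_block_totals_near_136(self, exp1_design):
        _, table = exp1_design
        per_block = table.groupby(
            ["participant_id", "condition", "block"]
        ).size()
        assert 120 <= per_block.mean() <= 152  # ~136 gaps per 32-stimulus block

    def test_lag_varies_and_is_wrapped(self, exp1_design):
        _, table = exp1_design
        lags = table["tacs_lag"].dropna().to_numpy()
        assert lags.std() > 0.5
        assert (lags >= -np.pi).all() and (lags < np.pi).all()

    def test_infeasible_packing_raises(self):
        cfg = DesignConfig(
            experiment="exp1", n_participants=1, stimulus_duration=5.0,
            gaps_per_stimulus=(5, 5), seed=0,
        )
        with pytest.raises(PackingError):
            gen_design(cfg)


class TestSimulateOutcomes:
    def test_flat_when_amplitude_zero(self, exp1_design):
        _, design = exp1_design
        out = simulate_outcomes(design, BehavioralModelParams(fm_amp=0.0), seed=1)
        b = PhaseBinning(9)
        rates = (
            out.assign(bin=b.assign(out["fm_phase"].to_numpy()))
            .groupby("bin")["accuracy"].mean()
        )
        assert rates.std() < 0.05

    def test_binned_rates_converge_to_analytic_probability(self):
        # law of large numbers: ~1e5 gaps per bin
        b = PhaseBinning(9)
        rng = np.random.default_rng(8)
        n = 900_000
        idx = rng.integers(0, 9, n)
        table = pd.DataFrame({
            "participant_id": 0, "session_id": 1, "condition": 1.0,
            "tacs_condition": "none", "gap_time": 5.0,
            "fm_phase": b.bin_centers[idx],
        })
        params = BehavioralModelParams(fm_amp=0.2, fm_pref_phase=np.pi / 2)
        out = simulate_outcomes(table, params, seed=2)
        emp = out.assign(bin=idx).groupby("bin")["accuracy"].mean().to_numpy()
        expected = 0.5 + 0.2 * np.cos(b.bin_centers - np.pi / 2)
        np.testing.assert_allclose(emp, expected, atol=0.01)

    def test_probabilities_clipped(self):
        table = pd.DataFrame({
            "participant_id": 0, "session_id": 1, "condition": 1.0,
            "tacs_condition": "none", "gap_time": 1.0,
            "fm_phase": [0.0, np.pi],
        })
        params = BehavioralModelParams(base_rate=0.5, fm_amp=0.9, clip_eps=0.02)
        p = hit_probability(table, params)
        assert p.max() <= 0.98 and p.min() >= 0.02
        with pytest.raises(ValueError):
            hit_probability(table, BehavioralModelParams(base_rate=0.5, fm_amp=0.9, clip_eps=0.0))

    def test_exp2_generated_effect_peaks_at_resonance(self):
        table, truth = ek.simulate_exp2(
            n_participants=1, seed=13, resonance_freqs={0: 2.0},
            tacs_amp_max=0.15, sham_rhythm_amp=0.0,
            config=DesignConfig(
                experiment="exp2", n_participants=1,
                conditions=(0.8, 2.0, 3.2, 4.4), n_blocks=5,
                stimuli_per_block=400, seed=13,
            ),
        )
        b = PhaseBinning(6)
        amps = {}
        for f, sub in table[table.tacs_condition == "active"].groupby("condition"):
            amps[float(f)] = ek.fit_binned(sub, b, "tacs_phase").amplitude
        assert max(amps, key=amps.get) == 2.0


class TestClassifyResponses:
    @pytest.mark.parametrize(
        "gaps, presses, acc, fa",
        [
            ([5.0], [5.5], [1], 0),          # press inside (100, 1500] ms
            ([5.0], [5.05], [0], 1),         # too early: miss + false alarm
            ([5.0], [6.5], [1], 0),          # boundary: exactly 1500 ms is a hit
            ([5.0], [5.1], [0], 1),          # boundary: exactly 100 ms is too early
            ([], [2.0], [], 1),              # press with no gap before
            ([3.0, 5.0], [3.5, 5.4, 9.0], [1, 1], 1),
            ([3.0, 4.6], [4.9], [0, 1], 0),  # credited to the eligible gap only
        ],
    )
    def test_scoring_rule(self, gaps, presses, acc, fa):
        a, _, n_fa = classify_responses(gaps, presses)
        assert list(a) == acc
        assert n_fa == fa

    def test_each_press_credits_one_gap(self):
        # two presses in one window: the second becomes a false alarm
        a, _, fa = classify_responses([5.0], [5.4, 5.6])
        assert list(a) == [1] and fa == 1

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            classify_responses([-1.0], [0.5])

    def test_roundtrip_with_generated_events(self, exp1_design):
        _, design = exp1_design
        out = simulate_outcomes(design, BehavioralModelParams(fm_amp=0.1), seed=3)
        sub = out[
            (out.participant_id == 0) & (out.condition == 11.0)
            & (out.block == 0) & (out.stimulus == 0)
        ].sort_values("gap_time")
        presses = response_events(sub, seed=4, fa_rate=0.05)
        acc, rts, _ = classify_responses(sub["gap_time"].to_numpy(), presses)
        np.testing.assert_array_equal(acc, sub["accuracy"].to_numpy())


class TestEegEpochs:
    def test_locked_component_and_noise_floor(self):
        es = simulate_eeg_epochs(2.0, n_trials=40, locked_amp=0.0, seed=5)
        from entrainkit.freqtag import itc_spectrum
        itc = itc_spectrum(es)
        bin_f = itc.nearest_bin(2.0)
        # chance-level coherence ~ 1/sqrt(n)
        assert itc.vector_length[0, bin_f] < 3.0 / np.sqrt(40)

    def test_full_coherence_without_noise(self):
        es = simulate_eeg_epochs(3.2, n_trials=10, noise_rms=0.0, seed=6)
        from entrainkit.freqtag import itc_spectrum
        itc = itc_spectrum(es)
        assert itc.vector_length[0, itc.nearest_bin(3.2)] == pytest.approx(1.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            simulate_eeg_epochs(300.0, fs=500.0)

    def test_determinism(self):
        a = simulate_eeg_epochs(2.0, n_trials=3, seed=9)
        b = simulate_eeg_epochs(2.0, n_trials=3, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
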