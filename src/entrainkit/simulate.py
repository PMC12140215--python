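"""Synthetic trial tables and EEG-like epochs for the three gap-detection designs.

The generators emulate the latent effect structure the estimators target:

* Experiment 1 — 2-Hz frequency-modulated (FM) noise at two modulation depths
  with concurrent 2-Hz tACS.  Hit probability is sinusoidally modulated by FM
  phase; the modulation amplitude is itself scaled by a cosine of the FM-tACS
  lag with a participant-specific optimal lag.
* Experiment 2 — unmodulated noise with tACS at 0.8/2/3.2/4.4 Hz plus sham.
  Hit probability is modulated by tACS phase with a Gaussian-in-log-frequency
  tuning around a latent per-participant resonance frequency; sham carries a
  weak endogenous rhythm that resets at stimulus onset.
* Experiment 3 — FM sounds at the four rates, 15 phase bins, no tACS; the FM
  modulation amplitude increases linearly with rate.

Hit probabilities are additive cosines clipped to [clip_eps, 1-clip_eps], so
the cosine-fit estimators are exact in expectation.  All outputs are fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circstats import PhaseBinning, wrap_phase

TACS_FREQUENCIES = (0.8, 2.0, 3.2, 4.4)
#: the eight equiprobable FM starting phases of each stimulus
START_PHASES = tuple(wrap_phase(np.arange(8) * np.pi / 4))

HIT_WINDOW = (0.1, 1.5)  # seconds after gap onset within which a press is a hit


class PackingError(RuntimeError):
    """Gap placement infeasible for the requested duration/spacing."""


@dataclass(frozen=True)
class DesignConfig:
    """Layout of one experiment's trial structure."""

    experiment: str = "exp1"  # exp1 | exp2 | exp3
    n_participants: int = 27
    conditions: tuple = (11.0, 39.0)  # depths (%), tACS freqs (Hz) or FM rates (Hz)
    n_blocks: int = 5
    stimuli_per_block: int = 32
    stimulus_duration: float = 20.0
    gaps_per_stimulus: tuple[int, int] = (3, 5)
    n_fm_phase_bins: int = 9
    n_tacs_lag_bins: int = 6
    fm_rate: float = 2.0
    tacs_rate: float = 2.0
    min_gap_spacing: float = 1.5
    edge_margin: float = 1.0  # no gaps in the first/last second
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_blocks < 1 or self.stimuli_per_block < 1:
            raise ValueError("counts must be >= 1")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")
        lo, hi = self.gaps_per_stimulus
        if not (1 <= lo <= hi):
            raise ValueError("invalid gaps_per_stimulus range")


@dataclass(frozen=True)
class BehavioralModelParams:
    """Latent hit-probability model: p = clip(base + A * cos(phase - pref))."""

    base_rate: float = 0.5
    # FM-phase modulation (Exp 1 / Exp 3)
    fm_amp: float | dict | None = None  # scalar, or dict keyed by condition label
    fm_pref_phase: float = 0.0
    amp_slope_per_hz: float = 0.0  # Exp 3: amplitude grows with FM rate
    # tACS-lag gain on the FM amplitude (Exp 1)
    tacs_modulation: float = 0.0
    lag_opt: float = 0.0
    # tACS-phase modulation with frequency tuning (Exp 2)
    tacs_amp_max: float | None = None
    resonance_freq: float = 2.0
    tuning_log_width: float = 0.35
    tacs_pref_phase: float = 0.0
    # endogenous rhythm in sham, resetting at stimulus onset (Exp 2)
    sham_rhythm_amp: float = 0.0
    sham_rhythm_freq: float = 2.0
    sham_rhythm_phase: float = 0.0
    clip_eps: float = 0.02

    def fm_amplitude(self, condition) -> float:
        if self.fm_amp is None:
            return 0.0
        if isinstance(self.fm_amp, dict):
            base = self.fm_amp[condition]
        else:
            base = float(self.fm_amp)
        try:
            f = float(condition)
        except (TypeError, ValueError):
            f = 0.0
        return base + self.amp_slope_per_hz * f if self.amp_slope_per_hz else base


# ---------------------------------------------------------------------------
# gap placement


def _place_gaps(rng, centers, start_phase, f, duration, min_spacing, margin, max_tries=200):
    """Gap onset times whose stimulus phase equals the assigned bin centers.

    Times solve wrap(2*pi*f*t + start_phase) == center within (margin,
    duration - margin), subject to a minimum spacing between successive gaps.
    """
    n = len(centers)
    if margin * 2 + (n - 1) * min_spacing >= duration:
        raise PackingError(f"cannot place {n} gaps with {min_spacing}s spacing in {duration}s")
    cands = []
    for c in centers:
        t0 = np.mod(c - start_phase, 2 * np.pi) / (2 * np.pi * f)
        times = t0 + np.arange(0, int(np.ceil(duration * f)) + 1) / f
        times = times[(times > margin) & (times < duration - margin)]
        if times.size == 0:
            raise PackingError(f"no admissible time for phase {c:.3f}")
        cands.append(times)
    for _ in range(max_tries):
        pairs = sorted(zip((cand[rng.integers(cand.size)] for cand in cands), range(n)))
        times = np.array([p[0] for p in pairs])
        if np.all(np.diff(times) >= min_spacing):
            idx = [p[1] for p in pairs]
            return times, [centers[i] for i in idx]
    raise PackingError("gap placement failed after max_tries attempts")


def _draw_gap_count(rng, lo, hi):
    # weighted toward 4-5 gaps so a 32-stimulus block totals ~136 gaps
    if (lo, hi) == (3, 5):
        return int(rng.choice([3, 4, 5], p=[0.15, 0.45, 0.40]))
    return int(rng.integers(lo, hi + 1))


def _gaps_for_stimulus(rng, cfg: DesignConfig, binning: PhaseBinning, bin_cycle):
    """Place one stimulus' gaps; assigns bins from a shuffled cyclic counter
    so occupancy stays near-uniform across bins."""
    n_gaps = _draw_gap_count(rng, *cfg.gaps_per_stimulus)
    bins = [next(bin_cycle) for _ in range(n_gaps)]
    centers = binning.bin_centers[bins]
    start_phase = START_PHASES[rng.integers(len(START_PHASES))]
    times, assigned = _place_gaps(
        rng, list(centers), start_phase, cfg.fm_rate, cfg.stimulus_duration,
        cfg.min_gap_spacing, cfg.edge_margin,
    )
    return times, np.array(assigned), start_phase


def _bin_cycler(rng, n_bins):
    """Yield bin indices, cycling through shuffled permutations of all bins."""
    while True:
        for b in rng.permutation(n_bins):
            yield int(b)


# ---------------------------------------------------------------------------
# design generation

_COLUMNS = [
    "participant_id", "session_id", "condition", "tacs_condition", "block",
    "stimulus", "gap_time", "fm_phase", "tacs_phase", "tacs_lag",
    "response_time", "accuracy",
]


def gen_design(config: DesignConfig) -> pd.DataFrame:
    """Trial table with phases populated and outcome columns empty (NaN)."""
    if config.experiment == "exp1":
        return _gen_exp1(config)
    if config.experiment == "exp2":
        return _gen_exp2(config)
    if config.experiment == "exp3":
        return _gen_exp3(config)
    raise ValueError(f"unknown experiment '{config.experiment}'")


def _rows_to_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["accuracy"] = np.nan
    df["response_time"] = np.nan
    return df


def _gen_exp1(cfg: DesignConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed)
    binning = PhaseBinning(cfg.n_fm_phase_bins)
    rows = []
    for p in range(cfg.n_participants):
        sham_block = int(rng.integers(cfg.n_blocks))  # constant across sessions
        for session, depth in enumerate(cfg.conditions, start=1):
            cyc = _bin_cycler(rng, cfg.n_fm_phase_bins)
            for block in range(cfg.n_blocks):
                sham = block == sham_block
                for s in range(cfg.stimuli_per_block):
                    times, centers, _ = _gaps_for_stimulus(rng, cfg, binning, cyc)
                    # FM and tACS run at the same rate, so their lag is one
                    # constant per stimulus, set by the random starting phase
                    lag = wrap_phase(rng.uniform(-np.pi, np.pi))
                    for t, c in zip(times, centers):
                        tacs_phase = wrap_phase(c - lag) if not sham else np.nan
                        rows.append((
                            p, session, depth, "sham" if sham else "active",
                            block, s, t, c, tacs_phase,
                            np.nan if sham else lag, np.nan, np.nan,
                        ))
    return _rows_to_frame(rows)


def _gen_exp2(cfg: DesignConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed)
    binning = PhaseBinning(cfg.n_fm_phase_bins)  # imaginary 2-Hz modulator bins
    conditions = ["sham"] + [f"{f:g}" for f in cfg.conditions]
    rows = []
    for p in range(cfg.n_participants):
        order = rng.permutation(len(conditions))
        for block, ci in enumerate(order):
            cond = conditions[ci]
            sham = cond == "sham"
            freq = None if sham else float(cond)
            cyc = _bin_cycler(rng, cfg.n_fm_phase_bins)
            for s in range(cfg.stimuli_per_block):
                times, centers, _ = _gaps_for_stimulus(rng, cfg, binning, cyc)
                tacs0 = rng.uniform(-np.pi, np.pi)
                for t, c in zip(times, centers):
                    tacs_phase = np.nan if sham else wrap_phase(2 * np.pi * freq * t + tacs0)
                    rows.append((
                        p, 1, cond, "sham" if sham else "active",
                        block, s, t, c, tacs_phase, np.nan, np.nan, np.nan,
                    ))
    return _rows_to_frame(rows)


def _gen_exp3(cfg: DesignConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed)
    binning = PhaseBinning(cfg.n_fm_phase_bins)
    rows = []
    for p in range(cfg.n_participants):
        rates = list(cfg.conditions)
        rng.shuffle(rates)
        for block, rate in enumerate(rates):
            cyc = _bin_cycler(rng, cfg.n_fm_phase_bins)
            rcfg = replace(cfg, fm_rate=float(rate))
            for s in range(cfg.stimuli_per_block):
                times, centers, _ = _gaps_for_stimulus(rng, rcfg, binning, cyc)
                for t, c in zip(times, centers):
                    rows.append((
                        p, 1, float(rate), "none", block, s, t, c,
                        np.nan, np.nan, np.nan, np.nan,
                    ))
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# outcome simulation


def hit_probability(table: pd.DataFrame, params: BehavioralModelParams) -> np.ndarray:
    """Latent per-gap hit probability before Bernoulli sampling."""
    p = np.full(len(table), params.base_rate)
    cond = table["condition"].to_numpy()
    active = table["tacs_condition"].to_numpy() == "active"
    if params.fm_amp is not None:
        amp = np.array([params.fm_amplitude(c) for c in cond])
        gain = np.ones(len(table))
        if params.tacs_modulation:
            lag = table["tacs_lag"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                g = 1.0 + params.tacs_modulation * np.cos(lag - params.lag_opt)
            gain = np.where(active & np.isfinite(lag), g, 1.0)
        p = p + amp * gain * np.cos(table["fm_phase"].to_numpy() - params.fm_pref_phase)
    if params.tacs_amp_max is not None:
        freq = np.array([float(c) if c != "sham" else np.nan for c in cond])
        with np.errstate(invalid="ignore"):
            tuning = params.tacs_amp_max * np.exp(
                -(np.log(freq / params.resonance_freq)) ** 2
                / (2 * params.tuning_log_width**2)
            )
            mod = tuning * np.cos(table["tacs_phase"].to_numpy() - params.tacs_pref_phase)
        p = p + np.where(active, np.nan_to_num(mod), 0.0)
        if params.sham_rhythm_amp:
            t = table["gap_time"].to_numpy()
            sham_mod = params.sham_rhythm_amp * np.cos(
                2 * np.pi * params.sham_rhythm_freq * t - params.sham_rhythm_phase
            )
            p = p + np.where(~active, sham_mod, 0.0)
    if params.clip_eps == 0 and np.any((p <= 0) | (p >= 1)):
        raise ValueError("hit probability saturates with clip_eps=0")
    return np.clip(p, params.clip_eps, 1.0 - params.clip_eps)


def simulate_outcomes(table: pd.DataFrame, params: BehavioralModelParams, seed=None) -> pd.DataFrame:
    """Draw per-gap accuracy ~ Bernoulli(p) and response times for hits."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    p = hit_probability(table, params)
    acc = (rng.random(len(table)) < p).astype(int)
    rt = np.where(acc == 1, rng.uniform(0.2, 1.0, len(table)), np.nan)
    out["accuracy"] = acc
    out["response_time"] = rt
    return out


# ---------------------------------------------------------------------------
# response-event scoring


def classify_responses(gap_times, press_times):
    """Score a stimulus' button presses against its gaps.

    A gap counts as a hit if some press falls in (gap + 0.1 s, gap + 1.5 s];
    each press is credited to at most one gap (earliest eligible gap wins,
    first press wins).  Presses crediting no gap are false alarms.

    Returns ``(accuracy, response_times, n_false_alarms)``.
    """
    gaps = np.asarray(gap_times, dtype=float)
    presses = np.sort(np.asarray(press_times, dtype=float))
    if np.any(gaps < 0) or np.any(presses < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(gaps) < 0):
        raise ValueError("gap times must be sorted")
    lo, hi = HIT_WINDOW
    acc = np.zeros(gaps.size, dtype=int)
    rts = np.full(gaps.size, np.nan)
    false_alarms = 0
    for press in presses:
        eligible = np.flatnonzero((acc == 0) & (press - gaps > lo) & (press - gaps <= hi))
        if eligible.size:
            g = eligible[0]
            acc[g] = 1
            rts[g] = press - gaps[g]
        else:
            false_alarms += 1
    return acc, rts, false_alarms


def response_events(stimulus_table: pd.DataFrame, seed=None, fa_rate=0.01):
    """Press-time stream consistent with a scored stimulus' rows.

    For every hit, one press at gap_time + response_time; additional spurious
    presses arrive as a Poisson process at ``fa_rate`` per second, placed
    outside every hit window so scoring round-trips exactly.
    """
    rng = np.random.default_rng(seed)
    gaps = stimulus_table["gap_time"].to_numpy()
    acc = stimulus_table["accuracy"].to_numpy()
    rts = stimulus_table["response_time"].to_numpy()
    duration = float(gaps.max() + 2.0)
    presses = list(gaps[acc == 1] + rts[acc == 1])
    n_fa = rng.poisson(fa_rate * duration)
    lo, hi = HIT_WINDOW
    made = 0
    while made < n_fa:
        t = rng.uniform(0, duration)
        if not np.any((t - gaps > lo) & (t - gaps <= hi)):
            presses.append(t)
            made += 1
    return np.array(sorted(presses))


# ---------------------------------------------------------------------------
# EEG-like epochs


@dataclass
class EpochSet:
    """Trials x channels x samples array with sampling rate and condition."""

    data: np.ndarray
    fs: float
    condition: float  # FM rate in Hz
    channel_labels: list[str]
    epoch_onset_phase: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[2] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.fs


DEFAULT_CHANNELS = ["F3", "Fz", "F4", "FC1", "FCz", "FC2", "C3", "Cz", "C4"]


def pink_noise(rng, n_samples, exponent=1.0, rms=1.0, shape=()):
    """1/f**exponent noise via spectral shaping, unit-RMS by default."""
    n_freq = n_samples // 2 + 1
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0
    scale = f ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    size = tuple(shape) + (n_freq,)
    spec = (rng.standard_normal(size) + 1j * rng.standard_normal(size)) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    current = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    current[current == 0] = 1.0
    return x / current * rms


def simulate_eeg_epochs(
    fm_rate: float,
    n_trials: int = 30,
    fs: float = 500.0,
    duration: float = 10.0,
    locked_amp: float = 1.0,
    noise_exponent: float = 1.0,
    noise_rms: float = 1.0,
    coherence: float = 1.0,
    onset_phase: float = 0.0,
    channel_labels=None,
    seed=None,
) -> EpochSet:
    """Epochs containing a phase-locked sinusoid at the FM rate in 1/f noise.

    ``coherence`` in [0, 1] sets the across-trial phase stability of the
    locked component: 1 means identical phase on every trial, 0 means phase
    uniform on the circle.
    """
    if fm_rate >= fs / 2:
        raise ValueError("fm_rate must be below the Nyquist frequency")
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(channel_labels) if channel_labels is not None else list(DEFAULT_CHANNELS)
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    jitter = rng.uniform(-np.pi, np.pi, size=n_trials) * (1.0 - coherence)
    signal = locked_amp * np.cos(
        2 * np.pi * fm_rate * t[None, None, :] + onset_phase + jitter[:, None, None]
    )
    signal = np.broadcast_to(signal, (n_trials, len(labels), n_samples)).copy()
    noise = (
        pink_noise(rng, n_samples, noise_exponent, noise_rms, shape=(n_trials, len(labels)))
        if noise_rms > 0
        else 0.0
    )
    return EpochSet(signal + noise, fs, fm_rate, labels, onset_phase)


# ---------------------------------------------------------------------------
# per-experiment conveniences with participant-level heterogeneity


def simulate_exp1(
    n_participants: int = 27,
    seed: int = 0,
    fm_amp=None,
    tacs_modulation: float = 0.4,
    base_rate: float = 0.5,
    pref_phase_center: float = 0.0,
    pref_phase_spread: float = 0.4,
    config: DesignConfig | None = None,
):
    """Full Experiment-1 dataset; returns (table, per-participant truth).

    Preferred FM phases scatter around a common center (listeners agree on
    when in the cycle detection is easiest), whereas the optimal tACS lag is
    uniform across participants (it depends on idiosyncratic anatomy).
    """
    cfg = config or DesignConfig(experiment="exp1", n_participants=n_participants, seed=seed)
    rng = np.random.default_rng(seed + 1)
    design = gen_design(cfg)
    fm_amp = fm_amp if fm_amp is not None else {11.0: 0.08, 39.0: 0.12}
    parts, truth = [], []
    for p, sub in design.groupby("participant_id", sort=True):
        pars = BehavioralModelParams(
            base_rate=base_rate,
            fm_amp=fm_amp,
            fm_pref_phase=wrap_phase(
                pref_phase_center + rng.normal(0.0, pref_phase_spread)
            ),
            tacs_modulation=tacs_modulation,
            lag_opt=rng.uniform(-np.pi, np.pi),
        )
        parts.append(simulate_outcomes(sub, pars, seed=rng.integers(2**31)))
        truth.append({"participant_id": p, "fm_pref_phase": pars.fm_pref_phase,
                      "lag_opt": pars.lag_opt, "tacs_modulation": tacs_modulation})
    return pd.concat(parts, ignore_index=True), pd.DataFrame(truth)


def simulate_exp2(
    n_participants: int = 24,
    seed: int = 0,
    tacs_amp_max: float = 0.12,
    sham_rhythm_amp: float = 0.03,
    resonance_freqs=None,
    config: DesignConfig | None = None,
):
    """Full Experiment-2 dataset; returns (table, per-participant truth)."""
    cfg = config or DesignConfig(
        experiment="exp2", n_participants=n_participants,
        conditions=TACS_FREQUENCIES, n_blocks=5, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    design = gen_design(cfg)
    parts, truth = [], []
    for p, sub in design.groupby("participant_id", sort=True):
        f_res = (
            float(resonance_freqs[p])
            if resonance_freqs is not None
            else float(np.exp(rng.uniform(np.log(0.8), np.log(4.4))))
        )
        pars = BehavioralModelParams(
            tacs_amp_max=tacs_amp_max,
            resonance_freq=f_res,
            tacs_pref_phase=rng.uniform(-np.pi, np.pi),
            sham_rhythm_amp=sham_rhythm_amp,
            sham_rhythm_freq=f_res,
        )
        parts.append(simulate_outcomes(sub, pars, seed=rng.integers(2**31)))
        truth.append({"participant_id": p, "resonance_freq": f_res,
                      "tacs_pref_phase": pars.tacs_pref_phase})
    return pd.concat(parts, ignore_index=True), pd.DataFrame(truth)


def simulate_exp3_eeg(
    n_participants: int = 12,
    seed: int = 0,
    rates=TACS_FREQUENCIES,
    n_trials: int = 30,
    locked_amp_base: float = 0.02,
    locked_amp_slope: float = 0.02,
    noise_rms: float = 1.0,
    coherence: float = 1.0,
) -> dict:
    """Synthetic EEG epoch sets per (participant, FM rate).

    The phase-locked component's amplitude grows linearly with FM rate
    (locked_amp_base + locked_amp_slope * rate) against unit-RMS 1/f noise,
    emulating stronger steady-state entrainment at faster rates.
    """
    rng = np.random.default_rng(seed)
    return {
        (p, float(r)): simulate_eeg_epochs(
            float(r),
            n_trials=n_trials,
            locked_amp=locked_amp_base + locked_amp_slope * float(r),
            noise_rms=noise_rms,
            coherence=coherence,
            seed=rng.integers(2**31),
        )
        for p in range(n_participants)
        for r in rates
    }


def simulate_exp3(
    n_participants: int = 12,
    seed: int = 0,
    fm_amp_base: float = 0.04,
    amp_slope_per_hz: float = 0.015,
    config: DesignConfig | None = None,
):
    """Full Experiment-3 behavioral dataset; returns (table, truth)."""
    cfg = config or DesignConfig(
        experiment="exp3", n_participants=n_participants,
        conditions=TACS_FREQUENCIES, n_blocks=4, stimuli_per_block=56,
        n_fm_phase_bins=15, fm_rate=2.0, tacs_rate=0.0, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    design = gen_design(cfg)
    parts, truth = [], []
    for p, sub in design.groupby("participant_id", sort=True):
        pars = BehavioralModelParams(
            fm_amp=fm_amp_base,
            amp_slope_per_hz=amp_slope_per_hz,
            fm_pref_phase=rng.uniform(-np.pi, np.pi),
        )
        parts.append(simulate_outcomes(sub, pars, seed=rng.integers(2**31)))
        truth.append({"participant_id": p, "fm_pref_phase": pars.fm_pref_phase})
    return pd.concat(parts, ignore_index=True), pd.DataFrame(truth)
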