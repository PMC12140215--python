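"""Experiment-1 pipeline: behavioral entrainment as a function of FM-tACS lag.

Per participant and modulation depth, gaps from the active-tACS blocks are
cross-binned by FM phase (9 bins) and FM-tACS lag (6 bins).  A first-level
cosine fit per lag bin yields entAmp-FM as a function of lag; a second-level
cosine fit over the six lag bins gives the individually optimal tACS lag.
Profiles are then realigned so the bin nearest the optimal lag sits at lag
zero; the realigned zero bin and its opposite are excluded, and the two bins
adjacent to zero (the optimal half-cycle, tACS+) and to pi (tACS-) are
averaged.  Contrasts against sham are z-scored against lag-shuffled
surrogates that rerun this entire pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .circstats import PhaseBinning, wrap_phase
from .cosinefit import (
    CosineFit,
    EmptyBinError,
    DegenerateNullError,
    fit_binned,
    fit_cosine,
    fit_cosine_many,
)

N_FM_BINS = 9
N_LAG_BINS = 6


def extract_tacs_phase(signal, fs, band=(1.0, 10.0), order=4):
    """Instantaneous phase of a recorded tACS channel.

    Zero-phase band-pass (4th-order Butterworth applied forward and backward)
    followed by the analytic-signal angle; a pure cosine at the stimulation
    frequency has phase zero at its peaks.
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 20:
        raise ValueError("sampling rate too low for a 1-10 Hz band-pass")
    if x.size < int(2 * fs):
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has undefined phase")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, x)
    return np.angle(hilbert(filtered))


def lag_binning(fm_phase, tacs_phase, n_bins: int = N_LAG_BINS):
    """FM-tACS lag = wrap(fm - tacs) and its bin index (6 equal bins)."""
    lag = wrap_phase(np.asarray(fm_phase, dtype=float) - np.asarray(tacs_phase, dtype=float))
    binning = PhaseBinning(n_bins)
    return lag, binning.assign(lag)


@dataclass
class LagProfile:
    """entAmp-FM per tACS-lag bin with its second-level fit and summaries."""

    lag_bin_centers: np.ndarray
    entamp_per_lag: np.ndarray
    first_level: list = field(default_factory=list)
    second_level_fit: CosineFit | None = None
    optimal_lag: float | None = None
    optimal_bin: int | None = None
    realigned_values: np.ndarray | None = None  # index = realigned bin position
    excluded: np.ndarray | None = None
    tacs_plus: float | None = None
    tacs_minus: float | None = None


def profile_entrainment_by_lag(
    table: pd.DataFrame,
    n_fm_bins: int = N_FM_BINS,
    n_lag_bins: int = N_LAG_BINS,
) -> LagProfile:
    """First-level cosine fits (over FM phase) for each tACS-lag bin.

    Every (FM bin, lag bin) cell must contain at least one gap; an empty cell
    raises :class:`EmptyBinError` naming the cell, which is the per-participant
    exclusion rule.
    """
    fm_binning = PhaseBinning(n_fm_bins)
    lag_bins = PhaseBinning(n_lag_bins)
    fm_idx = fm_binning.assign(table["fm_phase"].to_numpy())
    lag_idx = lag_bins.assign(table["tacs_lag"].to_numpy())
    acc = table["accuracy"].to_numpy(dtype=float)
    cell = lag_idx * n_fm_bins + fm_idx
    n = np.bincount(cell, minlength=n_lag_bins * n_fm_bins)
    if np.any(n == 0):
        empty = np.flatnonzero(n == 0)
        lag_b, fm_b = empty // n_fm_bins, empty % n_fm_bins
        raise EmptyBinError(
            f"empty (FM bin, lag bin) cells: {list(zip(fm_b.tolist(), lag_b.tolist()))}"
        )
    hits = np.bincount(cell, weights=acc, minlength=n_lag_bins * n_fm_bins)
    rates = (hits / n).reshape(n_lag_bins, n_fm_bins)
    fits = [fit_cosine(fm_binning.bin_centers, r) for r in rates]
    return LagProfile(
        lag_bin_centers=lag_bins.bin_centers,
        entamp_per_lag=np.array([f.amplitude for f in fits]),
        first_level=fits,
    )


def second_level_fit(profile: LagProfile) -> LagProfile:
    """Cosine fit of entAmp-FM over lag bins; its phase is the optimal lag."""
    fit = fit_cosine(profile.lag_bin_centers, profile.entamp_per_lag)
    profile.second_level_fit = fit
    profile.optimal_lag = fit.phase
    return profile


def _nearest_bin(optimal_lag: float, centers: np.ndarray) -> int:
    # ties (optimal exactly between two centers) break to the lower index
    d = np.abs(wrap_phase(optimal_lag - centers))
    return int(np.argmin(np.round(d, 12)))


def realign_profile(profile: LagProfile) -> LagProfile:
    """Rotate the lag profile so the bin nearest the optimal lag is lag 0.

    ``realigned_values[p]`` is the entAmp-FM at realigned lag p * 60 deg.
    The realigned zero bin and its opposite (pi) are excluded from further
    summaries to avoid selection bias from the alignment itself.
    """
    if profile.optimal_lag is None:
        raise ValueError("run second_level_fit before realigning")
    n = profile.lag_bin_centers.size
    opt_bin = _nearest_bin(profile.optimal_lag, profile.lag_bin_centers)
    pos = (np.arange(n) - opt_bin) % n
    realigned = np.empty(n)
    realigned[pos] = profile.entamp_per_lag
    excluded = np.zeros(n, dtype=bool)
    excluded[0] = True
    excluded[n // 2] = True
    profile.optimal_bin = opt_bin
    profile.realigned_values = realigned
    profile.excluded = excluded
    return profile


def half_cycle_summary(profile: LagProfile) -> tuple[float, float]:
    """(tACS+, tACS-): means of the two bins adjacent to lag 0 and to pi."""
    if profile.realigned_values is None:
        raise ValueError("realign the profile first")
    v = profile.realigned_values
    n = v.size
    if n != N_LAG_BINS:
        raise ValueError("half-cycle summary is defined for 6 lag bins")
    plus = float((v[1] + v[n - 1]) / 2.0)
    minus = float((v[n // 2 - 1] + v[n // 2 + 1]) / 2.0)
    profile.tacs_plus, profile.tacs_minus = plus, minus
    return plus, minus


def exp1_pipeline(active_table: pd.DataFrame) -> LagProfile:
    """Full first-level -> second-level -> realign -> half-cycle chain."""
    profile = profile_entrainment_by_lag(active_table)
    second_level_fit(profile)
    realign_profile(profile)
    half_cycle_summary(profile)
    return profile


@dataclass
class TacsEffect:
    """Half-cycle contrasts and their surrogate-normalized z-scores."""

    plus_minus_sham: float
    minus_minus_sham: float
    plus_minus_minus: float
    z_plus_minus_sham: float
    z_minus_minus_sham: float
    z_plus_minus_minus: float
    n_perm_used: int


def _pipeline_from_counts(rates, fm_centers, lag_centers):
    """Vectorized pipeline core from a (n_lag, n_fm) hit-rate matrix."""
    _, amps, _ = fit_cosine_many(fm_centers, rates)
    fit = fit_cosine(lag_centers, amps)
    opt_bin = _nearest_bin(fit.phase, lag_centers)
    n = lag_centers.size
    pos = (np.arange(n) - opt_bin) % n
    realigned = np.empty(n)
    realigned[pos] = amps
    plus = (realigned[1] + realigned[n - 1]) / 2.0
    minus = (realigned[n // 2 - 1] + realigned[n // 2 + 1]) / 2.0
    return plus, minus


def tacs_effect_zscores(
    participant_table: pd.DataFrame,
    n_perm: int = 1000,
    seed=None,
    n_fm_bins: int = N_FM_BINS,
    n_lag_bins: int = N_LAG_BINS,
) -> TacsEffect:
    """tACS half-cycle contrasts z-scored against lag-shuffled surrogates.

    ``participant_table`` holds one participant x modulation depth, including
    both sham and active rows.  Each surrogate shuffles the per-trial tACS lag
    labels (all other columns fixed) and reruns the complete binning,
    second-level fit, realignment and half-cycle pipeline.  Surrogates that
    leave a (FM bin, lag bin) cell empty are dropped from the null.
    """
    sham = participant_table[participant_table["tacs_condition"] == "sham"]
    active = participant_table[participant_table["tacs_condition"] == "active"]
    if len(sham) == 0 or len(active) == 0:
        raise ValueError("need both sham and active trials")
    sham_amp = fit_binned(sham, PhaseBinning(n_fm_bins), "fm_phase").amplitude

    fm_binning = PhaseBinning(n_fm_bins)
    lag_bins = PhaseBinning(n_lag_bins)
    fm_idx = fm_binning.assign(active["fm_phase"].to_numpy())
    lag_idx = lag_bins.assign(active["tacs_lag"].to_numpy())
    acc = active["accuracy"].to_numpy(dtype=float)
    n_cells = n_lag_bins * n_fm_bins

    def run(lidx):
        cell = lidx * n_fm_bins + fm_idx
        n = np.bincount(cell, minlength=n_cells)
        if np.any(n == 0):
            return None
        hits = np.bincount(cell, weights=acc, minlength=n_cells)
        rates = (hits / n).reshape(n_lag_bins, n_fm_bins)
        return _pipeline_from_counts(rates, fm_binning.bin_centers, lag_bins.bin_centers)

    observed = run(lag_idx)
    if observed is None:
        raise EmptyBinError("observed data leave a (FM bin, lag bin) cell empty")
    obs_plus, obs_minus = observed

    rng = np.random.default_rng(seed)
    sur = []
    for _ in range(n_perm):
        res = run(rng.permutation(lag_idx))
        if res is not None:
            sur.append(res)
    if len(sur) < 2:
        raise DegenerateNullError("too few valid surrogates")
    sur = np.asarray(sur)  # (n_valid, 2)
    contrasts = np.array([obs_plus - sham_amp, obs_minus - sham_amp, obs_plus - obs_minus])
    sur_contrasts = np.column_stack(
        [sur[:, 0] - sham_amp, sur[:, 1] - sham_amp, sur[:, 0] - sur[:, 1]]
    )
    sd = sur_contrasts.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise DegenerateNullError("surrogate contrast distribution has zero spread")
    z = (contrasts - sur_contrasts.mean(axis=0)) / sd
    return TacsEffect(*contrasts, *z, n_perm_used=len(sur))


def exp1_group_table(table: pd.DataFrame, n_perm: int = 1000, seed=None) -> pd.DataFrame:
    """Per participant x depth: sham amplitude, tACS+/-, contrasts and z-scores.

    Participants whose active trials leave an (FM bin, lag bin) cell empty are
    excluded with a recorded reason, mirroring the empty-cell exclusion rule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (p, cond), sub in table.groupby(["participant_id", "condition"], sort=True):
        try:
            active = sub[sub["tacs_condition"] == "active"]
            prof = exp1_pipeline(active)
            eff = tacs_effect_zscores(sub, n_perm=n_perm, seed=rng.integers(2**31))
            rows.append({
                "participant_id": p, "condition": cond, "excluded": False,
                "reason": "", "optimal_lag": prof.optimal_lag,
                "tacs_plus": prof.tacs_plus, "tacs_minus": prof.tacs_minus,
                "plus_minus_sham": eff.plus_minus_sham,
                "minus_minus_sham": eff.minus_minus_sham,
                "plus_minus_minus": eff.plus_minus_minus,
                "z_plus_minus_sham": eff.z_plus_minus_sham,
                "z_minus_minus_sham": eff.z_minus_minus_sham,
                "z_plus_minus_minus": eff.z_plus_minus_minus,
            })
        except EmptyBinError as err:
            rows.append({
                "participant_id": p, "condition": cond, "excluded": True,
                "reason": str(err),
            })
    return pd.DataFrame(rows)
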