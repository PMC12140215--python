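"""Frequency tagging of EEG epochs: evoked spectra, intertrial coherence,
cross-condition normalization, preferred-rate extraction, linear trends.

The evoked spectrum is the Hann-windowed Fourier amplitude of the
trial-averaged signal; activity that is not phase-locked across trials
averages out.  Intertrial phase coherence (ITC) is the resultant vector
length of per-trial spectral phases, 1 for perfect locking and about
sqrt(pi)/(2*sqrt(n)) for random phases.

Amplitude scaling uses the one-sided convention (x 2/N) divided by the Hann
coherent gain (0.5), so a phase-locked unit-amplitude sinusoid on a Fourier
bin reads out as 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal.windows import hann

from .simulate import DEFAULT_CHANNELS, EpochSet

logger = logging.getLogger(__name__)

FRONTOCENTRAL_CLUSTER = tuple(DEFAULT_CHANNELS)
HANN_COHERENT_GAIN = 0.5


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    condition: float
    channel_labels: list[str]
    evoked_amplitude: np.ndarray | None = None  # channels x freqs
    vector_length: np.ndarray | None = None  # channels x freqs

    def nearest_bin(self, freq: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - freq)))
        if not np.isclose(self.freqs[idx], freq, atol=1e-9):
            logger.warning(
                "frequency %.3f Hz off the spectral grid; using nearest bin %.3f Hz",
                freq, self.freqs[idx],
            )
        return idx


def _windowed_fft(data: np.ndarray, fs: float):
    n = data.shape[-1]
    w = hann(n, sym=False)
    spec = np.fft.rfft(data * w, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def evoked_spectrum(epochs: EpochSet) -> SpectrumResult:
    """Amplitude spectrum of the trial average (phase-locked activity)."""
    if epochs.n_trials < 2:
        raise ValueError("evoked_spectrum needs at least 2 trials")
    avg = epochs.data.mean(axis=0)  # channels x samples
    n = avg.shape[-1]
    freqs, spec = _windowed_fft(avg, epochs.fs)
    amp = np.abs(spec) * 2.0 / n / HANN_COHERENT_GAIN
    return SpectrumResult(freqs, epochs.condition, list(epochs.channel_labels),
                          evoked_amplitude=amp)


def itc_spectrum(epochs: EpochSet) -> SpectrumResult:
    """Intertrial phase coherence (resultant vector length) per channel/freq."""
    if epochs.n_trials < 2:
        warnings.warn("single trial: ITC is degenerately 1", stacklevel=2)
    freqs, spec = _windowed_fft(epochs.data, epochs.fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = spec / np.abs(spec)
    unit = np.nan_to_num(unit)
    R = np.abs(unit.mean(axis=0))  # channels x freqs
    return SpectrumResult(freqs, epochs.condition, list(epochs.channel_labels),
                          vector_length=R)


def cluster_average(result: SpectrumResult, channel_subset, which: str | None = None) -> np.ndarray:
    """Mean over a named channel subset, per frequency."""
    labels = result.channel_labels
    missing = [c for c in channel_subset if c not in labels]
    if missing:
        raise KeyError(f"unknown channels: {missing}")
    rows = [labels.index(c) for c in channel_subset]
    if which is None:
        which = "evoked_amplitude" if result.evoked_amplitude is not None else "vector_length"
    values = getattr(result, which)
    if values is None:
        raise ValueError(f"result carries no '{which}' values")
    return values[rows].mean(axis=0)


def normalize_across_conditions(values: np.ndarray, rates) -> np.ndarray:
    """Condition-specific value divided by its non-matching-condition mean.

    ``values[i, j]`` is the measure at frequency ``rates[j]`` while the
    stimulus was presented at ``rates[i]``.  The normalized entrainment at
    rate f is values[f, f] divided by the mean of values[c, f] over c != f,
    which cancels frequency-specific noise floors (1/f noise, bin leakage).
    """
    V = np.asarray(values, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if V.shape != (n, n):
        raise ValueError("values must be a conditions x frequencies square matrix")
    out = np.empty(n)
    for j in range(n):
        others = np.delete(V[:, j], j)
        denom = others.mean()
        if denom == 0:
            raise ZeroDivisionError(f"zero denominator at {rates[j]:g} Hz")
        out[j] = V[j, j] / denom
    return out


def preferred_rate(norm_values, rates) -> tuple[float, bool]:
    """Rate with the highest normalized value; ties break to the lower rate."""
    v = np.asarray(norm_values, dtype=float)
    r = np.asarray(rates, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("normalized values contain non-finite entries")
    best = float(v.max())
    winners = np.flatnonzero(v == best)
    tie = winners.size > 1
    if tie:
        logger.warning("tie among rates %s; reporting the lowest", r[winners])
    return float(r[winners.min()]), tie


def linear_trend(x, y) -> dict:
    """OLS of y on x with intercept: slope, R^2, F vs constant model, p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("x is constant; trend undefined")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "f": float(fit.fvalue),
        "p": float(fit.f_pvalue),
    }


def exp3_normalized_measures(
    epoch_sets: dict,
    rates,
    cluster=FRONTOCENTRAL_CLUSTER,
) -> pd.DataFrame:
    """Normalized amplitude and vector length per participant and FM rate.

    ``epoch_sets[(participant, rate)]`` maps to the :class:`EpochSet` recorded
    while that rate was presented.  For each participant a conditions x
    frequencies matrix of cluster-averaged values is assembled and normalized
    across conditions.
    """
    rates = [float(r) for r in rates]
    participants = sorted({p for p, _ in epoch_sets})
    rows = []
    for p in participants:
        amp = np.empty((len(rates), len(rates)))
        vl = np.empty((len(rates), len(rates)))
        for i, cond_rate in enumerate(rates):
            es = epoch_sets[(p, cond_rate)]
            ev = evoked_spectrum(es)
            itc = itc_spectrum(es)
            amp_c = cluster_average(ev, cluster)
            vl_c = cluster_average(itc, cluster, "vector_length")
            for j, f in enumerate(rates):
                b = ev.nearest_bin(f)
                amp[i, j] = amp_c[b]
                vl[i, j] = vl_c[b]
        namp = normalize_across_conditions(amp, rates)
        nvl = normalize_across_conditions(vl, rates)
        pref, tie = preferred_rate(nvl, rates)
        for j, f in enumerate(rates):
            rows.append({
                "participant_id": p, "fm_rate": f,
                "norm_amplitude": namp[j], "norm_vector_length": nvl[j],
                "preferred_rate": pref, "preferred_tie": tie,
            })
    return pd.DataFrame(rows)
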