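"""Experiment-2 pipeline: behavioral entrainment to tACS phase per frequency.

With no rhythm in the sound, gaps are binned by the tACS phase at gap onset
(six bins per frequency) and a cosine fit gives entAmp-tACS and the preferred
tACS phase.  The sham block provides a per-frequency baseline: an imaginary
oscillator assumed to reset to phase zero at stimulus onset, whose phase at
each gap is wrap(2*pi*f*gap_time); the cosine-fit amplitude over those bins
is the baseline rhythmic fluctuation.  The tACS effect is normalized as
(entAmp-tACS - baseline)/baseline; values above 1 (amplitude at least twice
baseline) flag a responder.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .circstats import PhaseBinning, rayleigh_test, wrap_phase
from .cosinefit import amplitude_null, fit_binned, fit_cosine, binned_hit_rates

N_PHASE_BINS = 6
BASELINE_FLOOR = 1e-3


class UnstableNormalizationWarning(UserWarning):
    """Baseline amplitude near zero; the normalized ratio is unreliable."""


def baseline_oscillator_phase(gap_time, f: float):
    """Phase of an imaginary oscillator resetting at stimulus onset."""
    if f <= 0:
        raise ValueError("oscillator frequency must be positive")
    return wrap_phase(2.0 * np.pi * f * np.asarray(gap_time, dtype=float))


def baseline_amplitude(
    sham_table: pd.DataFrame, f: float, n_bins: int = N_PHASE_BINS
) -> float:
    """Cosine-fit amplitude over imaginary-oscillator phase bins in sham."""
    phases = baseline_oscillator_phase(sham_table["gap_time"].to_numpy(), f)
    binning = PhaseBinning(n_bins)
    rates = binned_hit_rates(
        sham_table.assign(_osc_phase=phases), binning, "_osc_phase"
    )
    return fit_cosine(rates["center"].to_numpy(), rates["rate"].to_numpy()).amplitude


def normalized_effect(entamp_tacs: float, baseline_amp: float, floor: float = BASELINE_FLOOR) -> float:
    """(entAmp-tACS - baseline)/baseline; > 1 means at least twice baseline."""
    if baseline_amp <= 0:
        raise ValueError("baseline amplitude must be positive")
    if baseline_amp < floor:
        warnings.warn(
            f"baseline amplitude {baseline_amp:.2e} below {floor:g}; "
            "normalized effect is unstable",
            UnstableNormalizationWarning,
            stacklevel=2,
        )
    return (entamp_tacs - baseline_amp) / baseline_amp


def exp2_summary(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed=None,
    n_bins: int = N_PHASE_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant, per-frequency tACS effects plus group Rayleigh tests.

    Returns ``(effects, rayleigh)``: the first frame has one row per
    participant x tACS frequency with entAmp-tACS, preferred phase, baseline
    amplitude, normalized effect, responder flag and the z-score of
    entAmp-tACS against accuracy-shuffled surrogates; the second frame has
    one Rayleigh test per frequency on the preferred phases across
    participants.
    """
    rng = np.random.default_rng(seed)
    binning = PhaseBinning(n_bins)
    rows = []
    for p, sub in table.groupby("participant_id", sort=True):
        sham = sub[sub["tacs_condition"] == "sham"]
        active = sub[sub["tacs_condition"] == "active"]
        if len(sham) == 0:
            raise ValueError(f"participant {p} has no sham trials")
        freqs = sorted(float(c) for c in active["condition"].unique())
        if not freqs:
            raise ValueError(f"participant {p} has no active tACS trials")
        for f in freqs:
            cond = active[active["condition"].astype(float) == f]
            fit = fit_binned(cond, binning, "tacs_phase")
            base = baseline_amplitude(sham, f, n_bins)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnstableNormalizationWarning)
                eff = normalized_effect(fit.amplitude, base)
            unstable = base < BASELINE_FLOOR
            null = amplitude_null(
                binning.assign(cond["tacs_phase"].to_numpy()),
                cond["accuracy"].to_numpy(),
                binning,
                n_perm=n_perm,
                rng=rng,
            )
            sd = null.std(ddof=0)
            z = (fit.amplitude - null.mean()) / sd if sd > 0 else np.nan
            rows.append({
                "participant_id": p, "tacs_freq": f,
                "entamp_tacs": fit.amplitude, "pref_phase_tacs": fit.phase,
                "baseline_amp": base, "normalized_effect": eff,
                "responder": bool(eff > 1.0), "unstable_baseline": unstable,
                "z_entamp": z,
            })
    effects = pd.DataFrame(rows)
    ray_rows = []
    for f, sub in effects.groupby("tacs_freq"):
        R, z, pval = rayleigh_test(sub["pref_phase_tacs"].to_numpy())
        ray_rows.append({"tacs_freq": f, "R": R, "z": z, "p": pval, "n": len(sub)})
    return effects, pd.DataFrame(ray_rows)
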