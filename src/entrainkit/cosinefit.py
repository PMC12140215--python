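"""Single-cycle cosine fits to phase-binned hit rates, and permutation nulls.

The model fitted to hit rates r(phi_j) over bin centers phi_j is

    r = offset + amplitude * cos(phi - phase)

estimated by least squares in the linear sine/cosine basis, which has the
same optimum as a nonlinear fit of this model.  ``amplitude`` is the
behavioral-entrainment measure (entAmp); ``phase`` is the preferred phase.

Significance is assessed against surrogate distributions obtained by
shuffling single-gap accuracy values (0/1) while keeping the phase-bin labels
fixed, re-fitting the cosine on each shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import PhaseBinning, wrap_phase


class EmptyBinError(ValueError):
    """A phase bin required for fitting contains no trials."""


class DegenerateNullError(ValueError):
    """Surrogate distribution has zero spread; z-scoring is undefined."""


@dataclass
class CosineFit:
    offset: float
    amplitude: float
    phase: float
    fitted_values: np.ndarray
    rss: float
    degenerate: bool = False

    def predict(self, phi) -> np.ndarray:
        return self.offset + self.amplitude * np.cos(np.asarray(phi) - self.phase)


def _basis(centers: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(centers), np.cos(centers), np.sin(centers)])


def fit_cosine(bin_centers, rates) -> CosineFit:
    """Least-squares cosine fit over phase-bin centers.

    Requires at least 3 distinct centers (3 free parameters).  Amplitude is
    non-negative by construction; for perfectly flat data the fit is flagged
    degenerate and the phase is reported as 0.
    """
    c = wrap_phase(np.asarray(bin_centers, dtype=float))
    r = np.asarray(rates, dtype=float)
    c = np.atleast_1d(c)
    if c.shape != r.shape:
        raise ValueError("bin_centers and rates must have matching shapes")
    if np.unique(np.round(c, 12)).size < 3:
        raise ValueError("fit_cosine needs >= 3 distinct bin centers")
    X = _basis(c)
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    offset, b_cos, b_sin = beta
    amplitude = float(np.hypot(b_cos, b_sin))
    degenerate = amplitude < 1e-12
    phase = 0.0 if degenerate else float(np.arctan2(b_sin, b_cos))
    fitted = X @ beta
    rss = float(np.sum((r - fitted) ** 2))
    return CosineFit(float(offset), amplitude, phase, fitted, rss, degenerate)


def fit_cosine_many(bin_centers, rates_matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cosine fits: one fit per row of ``rates_matrix``.

    Returns (offsets, amplitudes, phases).  Used by the permutation engines
    where thousands of fits over the same bin centers are needed.
    """
    c = wrap_phase(np.asarray(bin_centers, dtype=float))
    R = np.atleast_2d(np.asarray(rates_matrix, dtype=float))
    pinv = np.linalg.pinv(_basis(np.atleast_1d(c)))  # (3, n_bins)
    B = R @ pinv.T  # (n_fits, 3)
    amps = np.hypot(B[:, 1], B[:, 2])
    phases = np.arctan2(B[:, 2], B[:, 1])
    return B[:, 0], amps, phases


def binned_hit_rates(
    table: pd.DataFrame,
    binning: PhaseBinning,
    phase_column: str = "fm_phase",
    require_full: bool = True,
) -> pd.DataFrame:
    """Hit rate and trial count per phase bin.

    Returns a frame indexed by bin with columns ``center``, ``n``, ``hits``,
    ``rate``.  Counts always sum to the number of input rows.  With
    ``require_full`` (the default) an empty bin raises :class:`EmptyBinError`,
    mirroring the exclusion of participants with unsampled bins; otherwise
    empty bins carry ``rate = NaN``.
    """
    if table["accuracy"].isna().any():
        raise ValueError("accuracy column contains missing values")
    idx = binning.assign(table[phase_column].to_numpy())
    acc = table["accuracy"].to_numpy(dtype=float)
    n = np.bincount(idx, minlength=binning.n_bins)
    hits = np.bincount(idx, weights=acc, minlength=binning.n_bins)
    if require_full and np.any(n == 0):
        empty = np.flatnonzero(n == 0).tolist()
        raise EmptyBinError(f"no trials in bin(s) {empty} of column '{phase_column}'")
    with np.errstate(invalid="ignore"):
        rate = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"center": binning.bin_centers, "n": n, "hits": hits.astype(int), "rate": rate}
    )


def fit_binned(table, binning, phase_column="fm_phase") -> CosineFit:
    """Convenience: bin, then cosine-fit the hit rates."""
    rates = binned_hit_rates(table, binning, phase_column)
    return fit_cosine(rates["center"].to_numpy(), rates["rate"].to_numpy())


@dataclass
class SurrogateDistribution:
    values: np.ndarray

    @property
    def n_perm(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=0))

    def percentile(self, q) -> float:
        return float(np.percentile(self.values, q))


def surrogate_null(
    table: pd.DataFrame,
    statistic_fn,
    n_perm: int = 1000,
    seed=None,
    group_cols=("participant_id", "session_id", "condition"),
) -> SurrogateDistribution:
    """Permutation null for any trial-table statistic.

    Each permutation shuffles the ``accuracy`` column across trials within
    participant x session x condition (phase labels and every other column
    stay fixed) and re-evaluates ``statistic_fn`` on the shuffled table.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [c for c in group_cols if c in table.columns]
    work = table.reset_index(drop=True).copy()
    acc = work["accuracy"].to_numpy()
    # positional row indices per shuffling group, computed once
    if cols:
        group_idx = [np.asarray(ix) for ix in work.groupby(cols, sort=False).indices.values()]
    else:
        group_idx = [np.arange(len(work))]
    vals = np.empty(n_perm)
    shuffled = acc.copy()
    for i in range(n_perm):
        for ix in group_idx:
            shuffled[ix] = acc[ix][rng.permutation(ix.size)]
        work["accuracy"] = shuffled
        vals[i] = statistic_fn(work)
    return SurrogateDistribution(vals)


def amplitude_null(
    bin_idx: np.ndarray,
    accuracy: np.ndarray,
    binning: PhaseBinning,
    n_perm: int = 1000,
    rng=None,
) -> np.ndarray:
    """Fast surrogate cosine amplitudes for one participant/condition.

    Vectorized equivalent of :func:`surrogate_null` with the fitted amplitude
    as the statistic: accuracy values are permuted across trials while the
    phase-bin labels stay fixed, then all permutations are re-fitted at once.
    """
    rng = np.random.default_rng(rng)
    acc = np.asarray(accuracy, dtype=float)
    idx = np.asarray(bin_idx, dtype=int)
    n = np.bincount(idx, minlength=binning.n_bins).astype(float)
    if np.any(n == 0):
        raise EmptyBinError("amplitude_null requires every bin to be sampled")
    perms = rng.permuted(np.broadcast_to(acc, (n_perm, acc.size)), axis=1)
    onehot = np.zeros((acc.size, binning.n_bins))
    onehot[np.arange(acc.size), idx] = 1.0
    hits = perms @ onehot  # (n_perm, n_bins)
    rates = hits / n
    _, amps, _ = fit_cosine_many(binning.bin_centers, rates)
    return amps


def zscore_vs_null(observed: float, null: SurrogateDistribution) -> float:
    """(observed - null mean) / null sd; errors on a zero-spread null."""
    # treat float-rounding spread from identical surrogate values as zero
    if null.sd <= 1e-12 * max(1.0, abs(null.mean)):
        raise DegenerateNullError("surrogate distribution has zero standard deviation")
    return (observed - null.mean) / null.sd
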