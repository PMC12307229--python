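"""Normalized lagged cross-correlation with permutation significance.

Used to ask whether two per-cell time series — central-pool actin and
protrusion actin, cell area, speed, bead displacement — co-vary, with which
sign, and at what temporal offset.  The correlation at each lag is a true
Pearson coefficient on the overlapping segments, so short tracks do not leak
edge artifacts into the tails of the lag curve.  Significance of the peak is
assessed against a circular-shift null, which preserves each series'
autocorrelation (an i.i.d. shuffle would be anti-conservative for the smooth
series typical of 30-s sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CrossCorrelation:
    lags: np.ndarray  # -L..+L
    r: np.ndarray  # Pearson r per lag; NaN where the overlap was degenerate
    peak_lag: int
    peak_r: float
    n_frames: int


@dataclass
class LagSignificance:
    p_value: float
    n_permutations: int
    observed: float
    null_mean: float
    null_q95: float
    seed: int


def _moving_median_detrend(x: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    return x - median_filter(x, size=window, mode="nearest")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def cross_correlate(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 10,
    detrend: bool = False,
) -> CrossCorrelation:
    """Pearson correlation of ``x_t`` with ``y_{t+lag}`` for each lag.

    Positive lag means ``y`` follows ``x``.  Each overlap segment is
    mean-centered and variance-normalized on the overlap itself.  Lags whose
    overlap has zero variance in either series are reported NaN; if every lag
    is degenerate the series are uninformative and an error is raised.  The
    peak is the lag with the largest ``|r|`` (ties go to the lag closest to
    zero, negative first).

    ``detrend=True`` removes a moving median (window ``2*max_lag+1``) from
    both series first — useful when slow drift swamps the fluctuations of
    interest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1D")
    n = x.size
    if n < 2 * max_lag + 4:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    if detrend:
        w = 2 * max_lag + 1
        x = _moving_median_detrend(x, w)
        y = _moving_median_detrend(y, w)
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: n + lag]
        r[i] = _pearson(a, b)
    if np.all(np.isnan(r)):
        raise ValueError("all lags degenerate (zero variance on every overlap)")
    # peak by |r|, ties toward lag 0, negative lag first on exact tie
    finite = ~np.isnan(r)
    order = np.lexsort((lags, np.abs(lags), -np.abs(np.where(finite, r, -np.inf))))
    peak_i = int(order[0])
    return CrossCorrelation(
        lags=lags, r=r, peak_lag=int(lags[peak_i]), peak_r=float(r[peak_i]),
        n_frames=n,
    )


def _corr_at_lags_matrix(x: np.ndarray, Y: np.ndarray, max_lag: int) -> np.ndarray:
    """max over lags of |Pearson(x_t, row_{t+lag})| for each row of ``Y``."""
    n = x.size
    best = np.zeros(Y.shape[0])
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, B = x[: n - lag], Y[:, lag:]
        else:
            a, B = x[-lag:], Y[:, : n + lag]
        ac = a - a.mean()
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(ac)
        nb = np.linalg.norm(Bc, axis=1)
        ok = (na > 0) & (nb > 0)
        rr = np.zeros(Y.shape[0])
        rr[ok] = np.abs(Bc[ok] @ ac) / (na * nb[ok])
        best = np.maximum(best, rr)
    return best


def _phase_surrogates(
    y: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Fourier phase-randomized copies of ``y`` (periodogram preserved)."""
    n = y.size
    F = np.fft.rfft(y)
    phases = rng.uniform(0, 2 * np.pi, size=(n_surrogates, F.size))
    phases[:, 0] = 0.0
    if n % 2 == 0:
        phases[:, -1] = 0.0
    return np.fft.irfft(np.abs(F)[None, :] * np.exp(1j * phases), n=n)


def lag_significance(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
    detrend: bool = False,
    null_model: str = "phase",
) -> LagSignificance:
    """Permutation p-value for the peak cross-correlation magnitude.

    The observed statistic is ``max_lag |r|``.  The default null randomizes
    the Fourier phases of ``y`` (Theiler surrogates): each surrogate keeps
    the series' periodogram — hence its autocorrelation, which an i.i.d.
    shuffle would destroy — while erasing any alignment with ``x``.  The
    p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_permutations + 1)``, so the smallest
    attainable p is ``1/(n_permutations + 1)``.

    ``null_model="circular"`` instead circularly shifts ``y`` by offsets
    drawn beyond ``max_lag``.  With short series this null is structurally
    anti-conservative: the shifted lag windows overlap each other but can
    never overlap the observed window, so the effective number of
    exchangeable draws is only about ``n / (2 max_lag + 1)`` regardless of
    ``n_permutations``.  It is provided for comparison; the phase null is
    calibrated (see the test suite's type-I check).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 * max_lag:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    if detrend:
        w = 2 * max_lag + 1
        x = _moving_median_detrend(x, w)
        y = _moving_median_detrend(y, w)
    cc = cross_correlate(x, y, max_lag=max_lag)
    observed = abs(cc.peak_r)
    rng = np.random.default_rng(seed)
    if null_model == "phase":
        null_y = _phase_surrogates(y, n_permutations, rng)
    elif null_model == "circular":
        # strictly beyond max_lag on both sides, otherwise a null shift can
        # reproduce the tested alignment exactly at the window edge
        shifts = rng.integers(max_lag + 1, n - max_lag, size=n_permutations)
        null_y = y[(np.arange(n)[None, :] + shifts[:, None]) % n]
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    null = _corr_at_lags_matrix(x, null_y, max_lag)
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return LagSignificance(
        p_value=float(p),
        n_permutations=n_permutations,
        observed=observed,
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        seed=seed,
    )


def pool_cross_correlations(curves: list[CrossCorrelation]) -> dict[str, np.ndarray]:
    """Pointwise mean and SEM of per-cell correlation curves.

    All curves must share a lag grid.  SEM is NaN wherever fewer than two
    cells contribute; per-lag contributing counts are returned.
    """
    if not curves:
        raise ValueError("nothing to pool")
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves have different lag grids")
    table = np.vstack([c.r for c in curves])
    n = np.sum(~np.isnan(table), axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(table, axis=0)
        sd = np.nanstd(table, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return {"lags": lags, "mean": mean, "sem": sem, "n": n}
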