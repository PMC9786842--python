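"""Previous-day integration of daily signals and the (n, λ) grid search.

A leaf carbon pool sampled on day t mixes assimilates from the preceding
days.  The integrated driver is a normalized geometric weighting

    X*_t = Σ_{i=0..n} λ^i · X_{t-i} / Σ_{i=0..n} λ^i,

where n is the memory length (days) and λ the previous-day weight (the
fraction of the current day's pool retained into the next day).  λ = 1
gives the unweighted (n+1)-day moving average, n = 0 the identity.  The
grid search correlates the integrated driver against a pool δ13C series
over n = 0..12, λ = 0.1..1.0 and reports the full Spearman surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Paper-convention grids.
N_GRID = tuple(range(0, 13))
LAMBDA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))

#: Pools whose needle generations may be combined, with the rule applied.
COMBINABLE_POOLS = {"sucrose": "mean", "WSC": "offset_then_mean"}


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ρ, two-sided p); rejects constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p); rejects constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def carryover_weights(n: int, lam: float, flat: bool = False) -> np.ndarray:
    """Normalized weights w_i for lags i = 0..n (w_0 is the current day).

    ``flat=True`` gives equal weights regardless of λ (the alternative
    reading of the weighting scheme, kept for sensitivity checks).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0 < lam <= 1):
        raise ValueError("λ must lie in (0, 1]")
    w = np.ones(n + 1) if flat else lam ** np.arange(n + 1, dtype=float)
    return w / w.sum()


def integrate_carryover(series: pd.Series, n: int, lam: float,
                        flat: bool = False) -> pd.Series:
    """Apply the carry-over weighting to a daily series.

    ``series`` is indexed by (normalized) daily timestamps and must be
    gap-free over each output date's look-back window; dates whose window
    is not fully covered are dropped, and if none survive an error is
    raised.
    """
    if series.empty:
        raise ValueError("empty input series")
    idx = pd.DatetimeIndex(series.index).normalize()
    s = pd.Series(series.to_numpy(dtype=float), index=idx).sort_index()
    full = s.reindex(pd.date_range(idx.min(), idx.max(), freq="D"))
    w = carryover_weights(n, lam, flat=flat)
    arr = full.to_numpy()
    out = np.full(arr.size, np.nan)
    # conv[j] = sum_i w[i]*arr[j-i]; only positions with a full window count,
    # and any NaN inside the window propagates
    conv = np.convolve(arr, w)
    out[n:] = conv[n:arr.size]
    res = pd.Series(out, index=full.index).dropna()
    # only keep the caller's dates
    res = res[res.index.isin(idx)]
    if res.empty:
        raise ValueError(
            f"no date has full {n}-day look-back coverage in the input series")
    return res


@dataclass
class CorrelationSurface:
    """Spearman (or Pearson) correlation over the (n, λ) grid."""

    table: pd.DataFrame        # columns: n, lam, rho, p, significant
    best_n: int
    best_lam: float
    best_rho: float
    best_p: float
    method: str = "spearman"
    alpha: float = 0.05


def grid_search(pool: pd.Series, driver: pd.Series,
                n_values=N_GRID, lam_values=LAMBDA_GRID,
                method: str = "spearman", flat: bool = False,
                min_overlap: int = 8, alpha: float = 0.05) -> CorrelationSurface:
    """Correlate a pool δ13C series against carry-over-integrated drivers.

    For every (n, λ) the daily ``driver`` is integrated and aligned to the
    pool's sampling dates; the same date alignment (the overlap at the
    largest n) is used for every cell so ρ values are comparable.  The
    argmax is reported with ties broken toward smaller n, then larger λ
    (the most parsimonious memory).
    """
    corr = {"spearman": spearman, "pearson": pearson}[method]
    pool_idx = pd.DatetimeIndex(pool.index).normalize()
    pool_s = pd.Series(pool.to_numpy(dtype=float), index=pool_idx).sort_index()

    n_values = sorted(int(n) for n in n_values)
    lam_values = sorted(float(l) for l in lam_values)
    # common alignment: dates with coverage at the largest n
    deepest = integrate_carryover(driver, n_values[-1], 1.0, flat=flat)
    dates = pool_s.index.intersection(deepest.index)
    if dates.size < min_overlap:
        raise ValueError(
            f"only {dates.size} overlapping dates after alignment "
            f"(need >= {min_overlap})")
    y = pool_s.loc[dates].to_numpy()

    rows = []
    for n in n_values:
        for lam in lam_values:
            x = integrate_carryover(driver, n, lam, flat=flat).loc[dates].to_numpy()
            rho, p = corr(x, y)
            rows.append((n, lam, rho, p, p < alpha))
    table = pd.DataFrame(rows, columns=["n", "lam", "rho", "p", "significant"])
    best = table.sort_values(["rho", "n", "lam"],
                             ascending=[False, True, False],
                             kind="mergesort").iloc[0]
    return CorrelationSurface(table=table, best_n=int(best["n"]),
                              best_lam=float(best["lam"]),
                              best_rho=float(best["rho"]),
                              best_p=float(best["p"]),
                              method=method, alpha=alpha)


def combine_generations(series_0n: pd.Series, series_1n: pd.Series,
                        pool_name: str, wsc_offset: float = 0.6,
                        force: bool = False) -> pd.Series:
    """Merge current-year (0N) and one-year-old (1N) needle series.

    Sucrose: plain average on shared dates (the generations agree after
    the initial flush).  WSC: the stable 0N-vs-1N enrichment (0.6 ‰ by
    default) is first subtracted from 0N, so the combined series
    represents 1N — the generation the gas-exchange chambers enclosed.
    Starch, pinitol and TOM keep generation-specific offsets that change
    through the season and are refused unless ``force=True``.
    Single-generation dates pass through unchanged.
    """
    rule = COMBINABLE_POOLS.get(pool_name)
    if rule is None and not force:
        raise ValueError(
            f"{pool_name}: generations have unstable δ13C offsets and are "
            "kept separate (use force=True to override)")
    s0 = pd.Series(series_0n.to_numpy(dtype=float),
                   index=pd.DatetimeIndex(series_0n.index).normalize())
    s1 = pd.Series(series_1n.to_numpy(dtype=float),
                   index=pd.DatetimeIndex(series_1n.index).normalize())
    if rule == "offset_then_mean":
        s0 = s0 - wsc_offset
    both = s0.index.intersection(s1.index)
    combined = pd.concat([
        (s0.loc[both] + s1.loc[both]) / 2.0,
        s0.loc[s0.index.difference(both)],
        s1.loc[s1.index.difference(both)],
    ]).sort_index()
    return combined
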