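"""Per-day lagged cross-correlation between delta-wilt and delta-stem series.

For a single plant-day with co-registered series the cross-correlation at lag
l is

    C(l) = [ (1/(n-|l|)) sum_t dstem(t-l) dwilt(t) - mu_s mu_w ] / (sigma_s sigma_w)

with GLOBAL (full-day) means and population standard deviations and the raw
lagged product sum divided by the per-lag overlap n - |l|.  A positive lag
pairs dwilt(t) with the earlier dstem(t-l): a peak at l > 0 means stem
variation precedes leaf wilting.  The peak (R_max, l_max) is reported both
unrestricted and restricted to l >= 0, and per-lag 99% confidence bounds use
the large-sample normal null z / sqrt(n - |l|).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignedDayPair",
    "CrossCorrelogram",
    "DaySkipped",
    "UndefinedCorrelationError",
    "align_day",
    "cross_correlation",
    "ci_bounds",
    "peak",
    "summarize_days",
]

IMAGE_WINDOW = (time(9, 0), time(17, 0))
MIN_OVERLAP = 10


class DaySkipped(Exception):
    """A plant-day that cannot enter the analysis; carries the reason."""


class UndefinedCorrelationError(ValueError):
    """Raised when a series has zero variance and C(l) is undefined."""


@dataclass
class AlignedDayPair:
    """Co-registered delta-stem and delta-wilt minute series for one plant-day."""

    date: object
    plant_id: str
    index: pd.DatetimeIndex
    dstem: np.ndarray
    dwilt: np.ndarray

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass
class CrossCorrelogram:
    """C(l) on a symmetric lag range with its null confidence bounds."""

    lags: np.ndarray
    c: np.ndarray
    n: int
    mu_stem: float
    mu_wilt: float
    sigma_stem: float
    sigma_wilt: float
    ci99: np.ndarray


def align_day(
    wilt: pd.Series,
    dstem: pd.Series,
    date,
    plant_id: str = "plant",
    window: tuple[time, time] = IMAGE_WINDOW,
    max_gap: int = 0,
) -> AlignedDayPair:
    """Intersect the two delta series on the camera window of one day.

    Raises :class:`DaySkipped` when either series is absent for the date, the
    intersection is empty, or interior minute gaps exceed ``max_gap``.
    """
    date = pd.Timestamp(date).date()

    def day_slice(series: pd.Series) -> pd.Series:
        sel = series[np.asarray(series.index.date) == date]
        tod = sel.index.time
        return sel[(tod >= window[0]) & (tod <= window[1])]

    wilt_day = day_slice(wilt)
    stem_day = day_slice(dstem)
    if wilt_day.empty:
        raise DaySkipped(f"{plant_id} {date}: no wilt data in window (missing images)")
    if stem_day.empty:
        raise DaySkipped(f"{plant_id} {date}: no stem data in window")
    common = wilt_day.index.intersection(stem_day.index)
    if len(common) == 0:
        raise DaySkipped(f"{plant_id} {date}: empty timestamp intersection")
    expected = pd.date_range(common[0], common[-1], freq="min")
    n_gaps = len(expected) - len(common)
    if n_gaps > max_gap:
        raise DaySkipped(f"{plant_id} {date}: {n_gaps} interior gap(s) exceed limit {max_gap}")
    return AlignedDayPair(
        date=date,
        plant_id=plant_id,
        index=common,
        dstem=stem_day.loc[common].to_numpy(dtype=float),
        dwilt=wilt_day.loc[common].to_numpy(dtype=float),
    )


def _lagged_product_mean(s: np.ndarray, w: np.ndarray, lag: int) -> float:
    n = len(s)
    if lag >= 0:
        prod = s[: n - lag] * w[lag:]
    else:
        prod = s[-lag:] * w[: n + lag]
    return float(prod.sum()) / (n - abs(lag))


def cross_correlation(
    pair: AlignedDayPair,
    max_lag: int = 60,
    min_overlap: int = MIN_OVERLAP,
) -> CrossCorrelogram:
    """C(l) for l in [-max_lag, +max_lag] with global-day normalisation."""
    s = pair.dstem
    w = pair.dwilt
    n = pair.n
    mu_s, mu_w = float(s.mean()), float(w.mean())
    sig_s, sig_w = float(s.std()), float(w.std())  # population (ddof=0)
    if sig_s == 0.0 or sig_w == 0.0:
        raise UndefinedCorrelationError(
            "zero variance in delta series; cross-correlation undefined"
        )
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.full(lags.shape, np.nan)
    for i, lag in enumerate(lags):
        if n - abs(lag) < min_overlap:
            continue
        c[i] = (_lagged_product_mean(s, w, int(lag)) - mu_s * mu_w) / (sig_s * sig_w)
    return CrossCorrelogram(
        lags=lags, c=c, n=n, mu_stem=mu_s, mu_wilt=mu_w,
        sigma_stem=sig_s, sigma_wilt=sig_w, ci99=ci_bounds(n, lags),
    )


def ci_bounds(n: int, lags, alpha: float = 0.01) -> np.ndarray:
    """Per-lag null bound z_{1-alpha/2} / sqrt(n - |l|) (nan where n <= |l|)."""
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    z = stats.norm.ppf(1 - alpha / 2)
    eff = n - np.abs(lags)
    out = np.full(lags.shape, np.nan)
    ok = eff > 0
    out[ok] = z / np.sqrt(eff[ok])
    return out


def peak(correlogram: CrossCorrelogram, restrict_nonneg: bool = False) -> tuple[float, int]:
    """(r_max, l_max): argmax of C(l); ties -> smallest |l|, then positive l."""
    lags = correlogram.lags
    c = correlogram.c
    sel = ~np.isnan(c)
    if restrict_nonneg:
        sel &= lags >= 0
    if not sel.any():
        raise ValueError("no defined lags to search")
    cmax = np.nanmax(c[sel])
    candidates = lags[sel & (c == cmax)]
    l_max = min(candidates, key=lambda l: (abs(l), 0 if l > 0 else 1))
    return float(cmax), int(l_max)


def summarize_days(
    plants: list[tuple[str, pd.Series, pd.Series]],
    env: pd.DataFrame,
    max_lag: int = 60,
    max_gap: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """One (R_max, l_max) row per plant-day, plus skip records.

    ``plants`` is a list of (plant_id, delta_wilt series, delta_stem series);
    ``env`` the minute-grid environment covering the same dates.  Daily PPFD
    and VPD means come from the 09:00-19:00 environmental window.

    Returns ``(summary, skipped)`` where summary has one row per plant-day
    passing alignment with columns r_max, l_max, r_max_nonneg, l_max_nonneg,
    n, mean_ppfd, mean_vpd.
    """
    from .env_regression import mean_env

    rows, skipped = [], []
    for plant_id, wilt, dstem in plants:
        dates = sorted(set(wilt.index.date) | set(dstem.index.date))
        for date in dates:
            try:
                pair = align_day(wilt, dstem, date, plant_id=plant_id, max_gap=max_gap)
                gram = cross_correlation(pair, max_lag=max_lag)
            except (DaySkipped, UndefinedCorrelationError) as err:
                skipped.append(str(err) if str(err) else f"{plant_id} {date}: {err!r}")
                continue
            r_max, l_max = peak(gram)
            r_nn, l_nn = peak(gram, restrict_nonneg=True)
            means = mean_env(env, date)
            rows.append(
                {
                    "plant": plant_id,
                    "date": date,
                    "r_max": r_max,
                    "l_max": l_max,
                    "r_max_nonneg": r_nn,
                    "l_max_nonneg": l_nn,
                    "n": pair.n,
                    "mean_ppfd": means["mean_ppfd"],
                    "mean_vpd": means["mean_vpd"],
                }
            )
    if not rows:
        raise ValueError(f"zero valid plant-days (skipped: {skipped})")
    return pd.DataFrame(rows), skipped
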