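"""Circadian rhythm metrics from hourly-aggregated wearable series.

Implements the nonparametric rhythm statistics (interdaily stability,
intradaily variability, interdaily coefficient of variation, M10/L5 and
relative amplitude, day-lag autocorrelation), a robust z-score peak
detector, and the extended (anti-logistically transformed) cosinor
model.

Nonparametric metrics take the hourly data as a ``(days, 24)`` matrix
(NaN marks hours with no data); formulas follow the standard printed
estimators exactly on complete data, and reduce to complete points /
complete successive pairs when hours are missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "interdaily_stability",
    "intradaily_variability",
    "interdaily_cv",
    "m10_l5_ra",
    "day_lag_autocorrelation",
    "detect_peak_signals",
    "peaks_per_day",
    "ExtendedCosinorModel",
    "CosinorResults",
    "fit_extended_cosinor",
]


def _as_day_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.size % 24:
            raise ValueError("1-D hourly series length must be a multiple of 24")
        x = x.reshape(-1, 24)
    return x


def interdaily_stability(x) -> float:
    """IS = (N * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2).

    Ratio of the variance of the mean 24-h profile to the total variance
    of the hour-aggregated data; 0 (no day-to-day regularity) to 1
    (identical days). ``x`` is a ``(days, 24)`` matrix or a flat series
    of whole days. Requires >= 2 days and a non-constant series;
    otherwise NaN.
    """
    x = _as_day_matrix(x)
    if x.shape[0] < 2:
        return np.nan
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n == 0:
        return np.nan
    grand = np.nansum(x) / n
    total_ss = np.nansum((x - grand) ** 2)
    if total_ss == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(x, axis=0)
    have = np.isfinite(profile)
    p = int(have.sum())
    profile_ss = np.sum((profile[have] - grand) ** 2)
    return float(n * profile_ss / (p * total_ss))


def intradaily_variability(x) -> float:
    """IV = (N * sum diff^2) / (n_pairs * sum (x_i - xbar)^2).

    Mean square of successive hourly differences normalized by the total
    variance; the flat series is scanned in time order and only
    successive pairs with both hours present contribute (n_pairs = N - 1
    on complete data, matching the printed formula). NaN on constant or
    too-short series.
    """
    x = _as_day_matrix(x).reshape(-1)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        return np.nan
    grand = x[finite].mean()
    total_ss = np.sum((x[finite] - grand) ** 2)
    if total_ss == 0:
        return np.nan
    pair = finite[:-1] & finite[1:]
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        return np.nan
    diffs = (x[1:] - x[:-1])[pair]
    return float(n * np.sum(diffs**2) / (n_pairs * total_ss))


def interdaily_cv(x) -> float:
    """ICV: the 24-hour mean of per-hour across-day coefficients of variation.

    For each clock hour the SD (ddof=1) and mean of that hour's values
    across days are formed; ICV is the mean of SD/mean over hours. Hours
    with a zero mean or fewer than two days are skipped with a warning
    and the divisor reduced.
    """
    x = _as_day_matrix(x)
    ratios = []
    skipped = 0
    for h in range(x.shape[1]):
        col = x[:, h]
        col = col[np.isfinite(col)]
        if len(col) < 2 or col.mean() == 0:
            skipped += 1
            continue
        ratios.append(col.std(ddof=1) / col.mean())
    if skipped:
        warnings.warn(
            f"ICV: {skipped} hour(s) skipped (zero mean or <2 days)",
            stacklevel=2,
        )
    if not ratios:
        return np.nan
    return float(np.mean(ratios))


def m10_l5_ra(x) -> tuple[float, float, float]:
    """M10, L5 and relative amplitude from the mean 24-h profile.

    M10 is the mean of the 10 consecutive most-active hours and L5 the
    mean of the 5 consecutive least-active hours, windows searched
    circularly over the average day; RA = (M10 - L5) / (M10 + L5), NaN
    when M10 + L5 = 0.
    """
    x = _as_day_matrix(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(x, axis=0)
    if not np.isfinite(profile).all():
        return np.nan, np.nan, np.nan
    wrapped = np.concatenate([profile, profile])
    m10 = max(wrapped[s:s + 10].mean() for s in range(24))
    l5 = min(wrapped[s:s + 5].mean() for s in range(24))
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom != 0 else np.nan
    return float(m10), float(l5), float(ra)


def day_lag_autocorrelation(series, points_per_day: int) -> float:
    """AC(k) = sum_{i<=N-k} (x_i - xbar)(x_{i+k} - xbar) / sum_i (x_i - xbar)^2.

    Day-length-lag autocorrelation with the full-sample denominator, as
    printed (numerator over N - k pairs, denominator over all N points;
    the mean is the full-sample mean). Missing points drop the pairs
    they appear in. NaN for constant series or when fewer than 2 days
    are available.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    k = int(points_per_day)
    if len(x) < 2 * k or k <= 0:
        return np.nan
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return np.nan
    grand = x[finite].mean()
    dev = np.where(finite, x - grand, 0.0)
    denom = np.sum(dev[finite] ** 2)
    if denom == 0:
        return np.nan
    pair = finite[:-k] & finite[k:]
    num = np.sum((dev[:-k] * dev[k:])[pair])
    return float(num / denom)


# -- robust z-score peak detection -------------------------------------

def detect_peak_signals(series, lag: int = 12, threshold: float = 2.0,
                        influence: float = 0.1) -> np.ndarray:
    """Streaming z-score peak detector (positive deviations only).

    A point is signalled when it exceeds the trailing moving mean of the
    *filtered* series by more than ``threshold`` trailing moving SDs
    over the previous ``lag`` points; signalled points enter the
    trailing statistics with weight ``influence``. Missing points (NaN)
    carry the last filtered value forward and are never signalled.

    Returns an int array of 0/1 signals aligned with the input.
    """
    y = np.asarray(series, dtype=float).reshape(-1)
    n = len(y)
    if n < lag + 1:
        raise ValueError("series shorter than lag")
    signals = np.zeros(n, dtype=int)
    filt = np.empty(n)
    last = 0.0
    for i in range(lag):
        v = y[i]
        filt[i] = v if np.isfinite(v) else last
        last = filt[i]
    # trailing window statistics maintained as running sums
    win = filt[:lag]
    s1 = float(win.sum())
    s2 = float((win * win).sum())
    inv_lag = 1.0 / lag
    y_list = y.tolist()
    for i in range(lag, n):
        mean = s1 * inv_lag
        var = s2 * inv_lag - mean * mean
        v = y_list[i]
        if var < 0:
            var = 0.0
        if v != v:  # NaN: carry the filter forward, never signal
            f = filt[i - 1]
        elif v > mean and (v - mean) * (v - mean) > threshold * threshold * var:
            signals[i] = 1
            f = influence * v + (1 - influence) * filt[i - 1]
        else:
            f = v
        filt[i] = f
        old = filt[i - lag]
        s1 += f - old
        s2 += f * f - old * old
    return signals


def peaks_per_day(series, bins_per_day: int, lag: int = 12,
                  threshold: float = 2.0, influence: float = 0.1
                  ) -> tuple[float, float]:
    """Mean and SD of the daily peak count.

    A peak is a maximal run of consecutive signalled points; it counts
    toward the day in which it starts. SD uses ddof=1 (NaN with a single
    day).
    """
    y = np.asarray(series, dtype=float).reshape(-1)
    if len(y) % bins_per_day:
        raise ValueError("series length must be a whole number of days")
    sig = detect_peak_signals(y, lag=lag, threshold=threshold, influence=influence)
    starts = np.flatnonzero(np.diff(np.concatenate([[0], sig])) == 1)
    n_days = len(y) // bins_per_day
    per_day = np.bincount(starts // bins_per_day, minlength=n_days)
    mean = float(per_day.mean())
    sd = float(per_day.std(ddof=1)) if n_days > 1 else np.nan
    return mean, sd


# -- extended cosinor ---------------------------------------------------

def _antilogistic(c, alpha, beta):
    return expit(beta * (c - alpha))


def _cosinor_curve(t, floor, height, acro, alpha, beta):
    c = np.cos(2 * np.pi * (t - acro) / 24.0)
    return floor + height * _antilogistic(c, alpha, beta)


@dataclass
class CosinorResults:
    """Fitted extended-cosinor parameters and goodness of fit.

    ``floor`` and ``height`` are the raw curve minimum-asymptote and
    range parameters; ``mesor`` is the rhythm-adjusted mean of the
    fitted curve, ``amplitude`` the curve maximum minus the mesor, and
    ``acrophase`` the clock time of the curve peak in [0, 24).
    """

    floor: float
    height: float
    acrophase: float
    alpha: float
    beta: float
    mesor: float
    amplitude: float
    pseudo_f: float
    converged: bool
    n_obs: int
    ssr: float
    ss_null: float

    def predict(self, t) -> np.ndarray:
        return _cosinor_curve(np.asarray(t, dtype=float), self.floor,
                              self.height, self.acrophase, self.alpha, self.beta)

    def summary(self) -> str:
        lines = [
            "Extended cosinor fit (anti-logistic transform)",
            f"  n observations : {self.n_obs}",
            f"  mesor          : {self.mesor:.4g}",
            f"  amplitude      : {self.amplitude:.4g}",
            f"  acrophase [h]  : {self.acrophase:.4g}",
            f"  alpha (width)  : {self.alpha:.4g}",
            f"  beta (steep.)  : {self.beta:.4g}",
            f"  pseudo-F       : {self.pseudo_f:.4g}",
            f"  converged      : {self.converged}",
        ]
        return "\n".join(lines)


class ExtendedCosinorModel:
    """Sigmoidally transformed cosine model of a diurnal rhythm.

    The fitted curve is ``y(t) = floor + height * F(cos(2*pi*(t - phi)/24))``
    with the anti-logistic transform ``F(c) = 1 / (1 + exp(-beta*(c - alpha)))``.
    ``alpha`` (in (-1, 1)) controls the relative width of the peak at
    half height and ``beta`` (> 0) the steepness of the rise and fall.

    Parameters
    ----------
    t : array-like
        Observation times in hours (any origin; only ``t mod 24``
        enters the curve).
    y : array-like
        Observed values (hourly-aggregated steps or heart rate).
    """

    N_PARAMS = 5

    def __init__(self, t, y):
        t = np.asarray(t, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        keep = np.isfinite(t) & np.isfinite(y)
        self.t, self.y = t[keep], y[keep]
        if len(self.y) < self.N_PARAMS + 1:
            raise ValueError("need more observations than parameters")
        if np.ptp(self.y) == 0:
            raise ValueError("constant series: cosinor fit is degenerate")
        # least-squares on per-time means (weighted by counts) is exact:
        # the model depends on t mod 24 only, so within-time scatter is
        # an additive constant of the objective.
        ut, inv = np.unique(np.round(self.t % 24.0, 9), return_inverse=True)
        self._ut = ut
        self._w = np.bincount(inv).astype(float)
        self._ybar = np.bincount(inv, weights=self.y) / self._w
        self._ss_within = float(np.sum(self.y**2)
                                - np.sum(self._w * self._ybar**2))

    def _residuals(self, params):
        f = _cosinor_curve(self._ut, *params)
        return self._sqrt_w * (self._ybar - f)

    def _jacobian(self, params):
        floor, height, acro, alpha, beta = params
        w = 2 * np.pi / 24.0
        arg = w * (self._ut - acro)
        c = np.cos(arg)
        f = _antilogistic(c, alpha, beta)
        g = f * (1 - f)          # dF/d(logit argument)
        J = np.empty((len(self._ut), 5))
        J[:, 0] = 1.0
        J[:, 1] = f
        J[:, 2] = height * beta * g * w * np.sin(arg)
        J[:, 3] = -height * beta * g
        J[:, 4] = height * g * (c - alpha)
        return -self._sqrt_w[:, None] * J

    def fit(self, acrophase_starts=(0.0, 6.0, 12.0, 18.0), tol: float = 1e-8
            ) -> CosinorResults:
        lo = np.array([-np.inf, 0.0, -24.0, -0.999, 1e-3])
        hi = np.array([np.inf, np.inf, 48.0, 0.999, 1e3])
        self._sqrt_w = np.sqrt(self._w)
        y0, y1 = float(self._ybar.min()), float(self._ybar.max())
        starts = list(acrophase_starts) + [float(self._ut[np.argmax(self._ybar)])]
        # rank the starts by their initial cost and refine the best two:
        # the acrophase basin is wide, so the cheapest start wins in
        # practice and the runner-up guards against a wrong basin.
        def _cost(phi0):
            r = self._residuals([y0, max(y1 - y0, 1e-6), phi0, 0.0, 2.0])
            return float(r @ r)
        starts = sorted(starts, key=_cost)[:2]
        best, success = None, False
        for phi0 in starts:
            p0 = np.array([y0, max(y1 - y0, 1e-6), phi0, 0.0, 2.0])
            try:
                res = least_squares(self._residuals, p0, jac=self._jacobian,
                                    bounds=(lo, hi), method="trf",
                                    xtol=tol, ftol=tol, gtol=tol)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
                success = bool(res.success)
                if best.cost <= 1e-20 * max(self._ss_within, 1.0):
                    break
        if best is None:
            return CosinorResults(*([np.nan] * 8), False, len(self.y),
                                  np.nan, np.nan)
        floor, height, acro, alpha, beta = best.x
        acro = float(acro % 24.0)
        grid = np.arange(0.0, 24.0, 1.0 / 60.0)
        curve = _cosinor_curve(grid, floor, height, acro, alpha, beta)
        mesor = float(curve.mean())
        amplitude = float(curve.max() - mesor)
        ssr = float(2.0 * best.cost + self._ss_within)
        n = len(self.y)
        ybar = float(np.mean(self.y))
        ss0 = float(np.sum((self.y - ybar) ** 2))
        q = self.N_PARAMS
        if ssr <= 0 or n <= q:
            pseudo_f = np.inf
        else:
            pseudo_f = ((ss0 - ssr) / (q - 1)) / (ssr / (n - q))
        return CosinorResults(
            floor=float(floor), height=float(height), acrophase=acro,
            alpha=float(alpha), beta=float(beta), mesor=mesor,
            amplitude=amplitude, pseudo_f=float(pseudo_f),
            converged=success, n_obs=n, ssr=ssr, ss_null=ss0,
        )


def fit_extended_cosinor(t, y, **kwargs) -> CosinorResults:
    """Convenience wrapper: fit :class:`ExtendedCosinorModel` on (t, y)."""
    return ExtendedCosinorModel(t, y).fit(**kwargs)
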