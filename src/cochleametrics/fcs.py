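"""Fluorescence correlation spectroscopy: correlation, model fitting, brightness.

The FCS workflow mirrors the experimental one: photon counts are recorded in a
confocal detection volume, the fluctuation autocorrelation

    G(tau) = <dF(t) dF(t+tau)> / <F>^2,   dF = F - <F>,

is computed per 10-s repetition, curves are averaged per location, and a 3-D
anomalous-diffusion model

    G(t) = (1/N) * [1 + (t/tau_D)^alpha]^-1 * [1 + (t/tau_D)^alpha / S^2]^-1/2

(optionally times a triplet factor ``1 + T/(1-T) * exp(-t/tau_T)``) is fitted.
``N`` is the mean number of molecules in the detection volume, ``tau_D`` the
mean diffusion (dwell) time, ``alpha`` the anomalous exponent (1 = normal
diffusion) and ``S`` the axial/lateral aspect ratio of the volume.  Molecular
brightness, the calcium proxy, is the background-corrected mean count rate
divided by N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

SITE_ORDER = ("TM1", "TM2", "TM3", "EndoL")

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "AnomalousDiffusionFit",
    "BrightnessResult",
    "autocorrelate",
    "multi_tau_lags",
    "average_correlations",
    "model_G",
    "fit_anomalous_diffusion",
    "fit_preparation",
    "molecular_brightness",
    "site_profile",
    "SITE_ORDER",
]


@dataclass
class PhotonTrace:
    """Binned photon counts from one FCS recording.

    ``background_rate`` is the pre-injection count rate (photons/s) measured
    before the indicator is present; it is subtracted before brightness is
    computed.
    """

    counts: np.ndarray
    bin_width: float
    background_rate: float = 0.0
    site_label: str | None = None
    repetition_index: int | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    @property
    def mean_count_rate(self) -> float:
        return float(self.counts.mean()) / self.bin_width


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # seconds, strictly increasing, all > 0
    G: np.ndarray
    mean_count_rate: float
    n_repetitions_averaged: int = 1
    G_sd: np.ndarray | None = None  # pointwise SD of the mean across repetitions

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have matching shapes")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.lags <= 0):
            raise ValueError("lag-zero (shot-noise) point is excluded; lags must be > 0")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")


@dataclass
class AnomalousDiffusionFit:
    N: float
    tau_D: float
    alpha: float
    S: float
    S_fitted: bool = False
    triplet_fraction: float = 0.0
    triplet_tau: float = 0.0
    included_triplet: bool = False
    residual_norm: float = np.nan
    covariance: np.ndarray | None = None
    param_names: tuple[str, ...] = ()
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.N > 0 and self.tau_D > 0 and self.S > 0):
                raise ValueError("N, tau_D, S must be positive")
            if not (0 < self.alpha <= 1):
                raise ValueError("alpha must lie in (0, 1]")
            if not (0 <= self.triplet_fraction < 1):
                raise ValueError("triplet fraction must lie in [0, 1)")

    def stderr(self, name: str) -> float:
        if self.covariance is None or name not in self.param_names:
            return np.nan
        i = self.param_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        est = {"N": self.N, "tau_D": self.tau_D, "alpha": self.alpha,
               "S": self.S, "T": self.triplet_fraction, "tau_T": self.triplet_tau}[name]
        se = self.stderr(name)
        z = norm.ppf(0.5 + level / 2)
        return est - z * se, est + z * se


@dataclass
class BrightnessResult:
    brightness: float  # photons / s / molecule
    corrected_rate: float  # photons / s
    N_used: float
    background_clipped: bool = False
    site_label: str | None = None


def multi_tau_lags(n_bins: int, lags_per_octave: int = 16, max_lag_fraction: float = 0.25) -> np.ndarray:
    """Quasi-logarithmic multi-tau lag grid, in units of bins.

    The first ``2*m`` lags are linearly spaced at the bin width; each later
    octave contributes ``m`` lags at doubled spacing, up to
    ``max_lag_fraction * n_bins`` so every lag retains adequate averaging.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    m = int(lags_per_octave)
    max_lag = max(1, int(n_bins * max_lag_fraction))
    lags = list(range(1, min(2 * m, max_lag) + 1))
    spacing, last = 2, lags[-1] if lags else 0
    while last + spacing <= max_lag:
        for _ in range(m):
            last += spacing
            if last > max_lag:
                break
            lags.append(last)
        spacing *= 2
    return np.array(sorted(set(lags)), dtype=int)


def _raw_autocorr(delta: np.ndarray) -> np.ndarray:
    """Full linear autocorrelation sums r_k = sum_t d_t d_{t+k} via FFT."""
    n = delta.size
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(delta, nfft)
    r = np.fft.irfft(f * np.conj(f), nfft)[:n]
    return r


def autocorrelate(
    trace: PhotonTrace,
    scheme: Literal["direct", "multi_tau"] = "multi_tau",
    max_lag_fraction: float = 0.25,
    lags_per_octave: int = 16,
    mean: float | None = None,
) -> CorrelationCurve:
    """Fluctuation autocorrelation of a photon trace.

    Both schemes evaluate the same exact estimator

        G(k) = [1/(n-k) * sum_t dF_t dF_{t+k}] / mean(F)^2 ;

    ``direct`` returns it on every lag up to ``max_lag_fraction * n``, while
    ``multi_tau`` returns it on the quasi-logarithmic multi-tau grid (the grids
    agree exactly at shared lags; the log grid merely spans the decades a
    10-s trace supports without the O(n) point count).

    ``mean`` optionally supplies an externally estimated mean count per bin
    (e.g. pooled over the consecutive repetitions recorded at one location).
    Using a pooled mean shrinks the finite-record normalisation bias — the
    systematic depression of G at lags approaching the record length that
    arises when each short trace is normalised by its own mean — by the number
    of repetitions pooled.
    """
    counts = np.asarray(trace.counts, dtype=float)
    n = counts.size
    if n < 2:
        raise ValueError("trace must have at least 2 bins")
    mean = counts.mean() if mean is None else float(mean)
    if mean == 0:
        raise ValueError("zero-mean trace: correlation normalisation undefined")
    delta = counts - mean
    if scheme == "direct":
        lag_bins = np.arange(1, max(1, int(n * max_lag_fraction)) + 1)
    elif scheme == "multi_tau":
        lag_bins = multi_tau_lags(n, lags_per_octave, max_lag_fraction)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    r = _raw_autocorr(delta)
    G = r[lag_bins] / (n - lag_bins) / mean**2
    return CorrelationCurve(
        lags=lag_bins * trace.bin_width,
        G=G,
        mean_count_rate=mean / trace.bin_width,
        n_repetitions_averaged=1,
    )


def average_correlations(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of correlation curves sharing a lag grid.

    Mirrors the per-location averaging over consecutive 10-s repetitions; the
    pointwise SD of the mean is retained for use as fit weights.
    """
    if len(curves) == 0:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags, rtol=0, atol=0):
            raise ValueError("mismatched lag grids")
    Gs = np.stack([c.G for c in curves])
    n_rep = sum(c.n_repetitions_averaged for c in curves)
    G_sd = Gs.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) >= 3 else None
    return CorrelationCurve(
        lags=lags.copy(),
        G=Gs.mean(axis=0),
        mean_count_rate=float(np.mean([c.mean_count_rate for c in curves])),
        n_repetitions_averaged=n_rep,
        G_sd=G_sd,
    )


def model_G(
    t: np.ndarray | float,
    N: float,
    tau_D: float,
    alpha: float = 1.0,
    S: float = 5.0,
    T: float = 0.0,
    tau_T: float = 1e-5,
) -> np.ndarray | float:
    """3-D anomalous-diffusion correlation model, optional triplet factor."""
    t = np.asarray(t, dtype=float)
    u = (t / tau_D) ** alpha
    g = (1.0 / N) / (1.0 + u) / np.sqrt(1.0 + u / S**2)
    if T > 0:
        g = g * (1.0 + T / (1.0 - T) * np.exp(-t / tau_T))
    return g if g.ndim else float(g)


def _initial_guess(curve: CorrelationCurve) -> tuple[float, float]:
    G0 = curve.G[0]
    if G0 <= 0:
        G0 = max(np.max(curve.G), 1e-6)
    N0 = 1.0 / G0
    below = np.nonzero(curve.G <= G0 / 2)[0]
    tau0 = curve.lags[below[0]] if below.size else curve.lags[-1]
    return max(N0, 1e-6), float(tau0)


def fit_anomalous_diffusion(
    curve: CorrelationCurve,
    fix_S: float | None = 5.0,
    allow_triplet: bool = False,
    fix_alpha: float | None = None,
    weights: np.ndarray | None = None,
    aic_margin: float = 4.0,
) -> AnomalousDiffusionFit:
    """Weighted least-squares fit of the anomalous-diffusion model.

    ``fix_S`` pins the aspect ratio (fitting S jointly with alpha is
    ill-conditioned); pass ``None`` to fit it.  When ``allow_triplet`` is set,
    a triplet term is *included* only if it improves AIC by at least
    ``aic_margin`` and the fitted triplet time is faster than ``tau_D / 10``;
    otherwise the diffusion-only fit is returned.

    Weights default to the inverse pointwise SD across repetitions when the
    curve carries one (>= 3 repetitions averaged), else the fit is unweighted.
    """
    t, G = curve.lags, curve.G
    if t.size < 5:
        raise ValueError("too few lag points to fit")
    sigma = None
    if weights is not None:
        sigma = 1.0 / np.asarray(weights, dtype=float)
    elif curve.G_sd is not None and np.all(curve.G_sd > 0):
        sigma = curve.G_sd

    N0, tau0 = _initial_guess(curve)

    def run(p0, lo, hi, fun):
        popt, pcov = curve_fit(
            fun, t, G, p0=p0, sigma=sigma, bounds=(lo, hi),
            maxfev=10000, xtol=1e-12, ftol=1e-12, gtol=1e-12, method="trf",
        )
        resid = fun(t, *popt) - G
        if sigma is not None:
            resid = resid / sigma
        rss = float(resid @ resid)
        n = t.size
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * len(popt)
        return popt, pcov, rss, aic

    names: list[str] = ["N", "tau_D"]
    p0: list[float] = [N0, tau0]
    lo: list[float] = [1e-9, 1e-9]
    hi: list[float] = [1e12, 1e6]
    if fix_alpha is None:
        names.append("alpha"); p0.append(1.0); lo.append(0.05); hi.append(1.0)
    if fix_S is None:
        names.append("S"); p0.append(5.0); lo.append(0.5); hi.append(100.0)

    def base_model(tt, *params):
        d = dict(zip(names, params))
        return model_G(tt, d["N"], d["tau_D"],
                       d.get("alpha", fix_alpha if fix_alpha is not None else 1.0),
                       d.get("S", fix_S if fix_S is not None else 5.0))

    try:
        popt, pcov, rss, aic = run(p0, lo, hi, base_model)
    except RuntimeError as exc:  # non-convergence flagged, never silent
        return AnomalousDiffusionFit(
            N=np.nan, tau_D=np.nan, alpha=np.nan, S=fix_S or np.nan,
            converged=False, message=f"diffusion fit failed: {exc}",
        )

    best = dict(zip(names, popt))
    best_names, best_cov, best_rss = tuple(names), pcov, rss
    included_triplet = False
    T_hat, tauT_hat = 0.0, 0.0

    if allow_triplet:
        tnames = names + ["T", "tau_T"]

        def trip_model(tt, *params):
            d = dict(zip(tnames, params))
            return model_G(tt, d["N"], d["tau_D"],
                           d.get("alpha", fix_alpha if fix_alpha is not None else 1.0),
                           d.get("S", fix_S if fix_S is not None else 5.0),
                           T=d["T"], tau_T=d["tau_T"])

        try:
            tp0 = list(popt) + [0.1, max(t[0], best["tau_D"] / 100)]
            tlo = list(lo) + [0.0, t[0] / 10]
            thi = list(hi) + [0.8, best["tau_D"]]
            tpopt, tpcov, trss, taic = run(tp0, tlo, thi, trip_model)
            td = dict(zip(tnames, tpopt))
            # selection rule: decisive AIC gain and a genuinely fast triplet
            if taic <= aic - aic_margin and td["tau_T"] < td["tau_D"] / 10:
                best, best_names, best_cov, best_rss = td, tuple(tnames), tpcov, trss
                included_triplet = True
                T_hat, tauT_hat = td["T"], td["tau_T"]
        except RuntimeError:
            pass  # triplet variant declined; diffusion-only fit stands

    return AnomalousDiffusionFit(
        N=float(best["N"]),
        tau_D=float(best["tau_D"]),
        alpha=float(best.get("alpha", fix_alpha if fix_alpha is not None else 1.0)),
        S=float(best.get("S", fix_S if fix_S is not None else 5.0)),
        S_fitted=fix_S is None,
        triplet_fraction=float(T_hat),
        triplet_tau=float(tauT_hat),
        included_triplet=included_triplet,
        residual_norm=float(np.sqrt(best_rss)),
        covariance=best_cov,
        param_names=best_names,
    )


def fit_preparation(
    traces: Sequence[PhotonTrace],
    fix_S: float | None = 5.0,
    fix_alpha: float | None = None,
    allow_triplet: bool = False,
    lag_max: float | None = None,
    scheme: Literal["direct", "multi_tau"] = "multi_tau",
) -> dict:
    """Analyse the consecutive repetitions recorded at one location.

    Mirrors the experimental workflow: each ~10-s repetition is correlated
    (normalised by the pooled mean across repetitions, which suppresses the
    finite-record normalisation bias), the curves are averaged, and the model
    is fitted to the averaged curve.  ``lag_max`` defaults to 2% of one
    repetition's duration: beyond that the single-record correlation estimate
    is dominated by finite-record noise and residual bias.

    Parameter uncertainty is taken from the scatter of per-repetition fits
    (t-based standard error of the mean), which is robust to the strong
    correlation of residuals across lags that makes curvature-based CIs from a
    single averaged curve overconfident.  Fits here are unweighted: pointwise
    variance estimates from a handful of repetitions are noisy enough that
    inverse-variance weighting measurably biases the diffusion time.

    Returns a dict with the averaged-curve fit, per-repetition estimates,
    95% CIs for N and tau_D, and the brightness result.
    """
    if len(traces) == 0:
        raise ValueError("no repetitions supplied")
    if lag_max is None:
        lag_max = 0.02 * traces[0].duration
    pooled_mean = float(np.mean([t.counts.mean() for t in traces]))
    curves = [autocorrelate(t, scheme, mean=pooled_mean) for t in traces]
    avg = average_correlations(curves)

    def clip(c: CorrelationCurve) -> CorrelationCurve:
        keep = c.lags <= lag_max
        return CorrelationCurve(c.lags[keep], c.G[keep], c.mean_count_rate,
                                c.n_repetitions_averaged)

    kwargs = dict(fix_S=fix_S, fix_alpha=fix_alpha, allow_triplet=allow_triplet)
    fit = fit_anomalous_diffusion(clip(avg), **kwargs)
    per_rep = []
    for c in curves:
        try:
            f = fit_anomalous_diffusion(clip(c), **kwargs)
            if f.converged:
                per_rep.append(f)
        except (ValueError, RuntimeError):
            continue
    ci = {}
    if len(per_rep) >= 3:
        from scipy.stats import t as t_dist

        tq = t_dist.ppf(0.975, len(per_rep) - 1)
        for name in ("N", "tau_D", "alpha"):
            vals = np.array([getattr(f, name) for f in per_rep])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            center = getattr(fit, name)
            ci[name] = (center - tq * se, center + tq * se)
    else:  # too few repetitions: fall back to curvature-based intervals
        for name in ("N", "tau_D"):
            ci[name] = fit.conf_int(name)

    rate = pooled_mean / traces[0].bin_width
    background = traces[0].background_rate
    corrected = max(rate - background, 0.0)
    brightness = BrightnessResult(
        brightness=corrected / fit.N if fit.converged else np.nan,
        corrected_rate=corrected,
        N_used=fit.N,
        background_clipped=rate < background,
        site_label=traces[0].site_label,
    )
    return {
        "fit": fit,
        "curve": avg,
        "per_repetition_fits": per_rep,
        "conf_int": ci,
        "mean_count_rate": rate,
        "brightness": brightness,
    }


def molecular_brightness(trace: PhotonTrace, fit: AnomalousDiffusionFit) -> BrightnessResult:
    """Background-corrected count rate per molecule (the calcium proxy)."""
    if not fit.converged:
        raise ValueError("cannot compute brightness from a non-converged fit")
    rate = trace.mean_count_rate
    corrected = rate - trace.background_rate
    clipped = False
    if corrected < 0:
        warnings.warn("background exceeds mean count rate; brightness floored at 0")
        corrected, clipped = 0.0, True
    return BrightnessResult(
        brightness=corrected / fit.N,
        corrected_rate=corrected,
        N_used=fit.N,
        background_clipped=clipped,
        site_label=trace.site_label,
    )


def site_profile(results: Mapping[str, BrightnessResult] | Sequence[BrightnessResult]) -> pd.DataFrame:
    """Per-preparation site table (TM1, TM2, TM3, EndoL order), missing sites explicit."""
    if not isinstance(results, Mapping):
        pairs = [(r.site_label, r) for r in results]
        labels = [s for s, _ in pairs]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate site labels within one preparation")
        results = dict(pairs)
    rows = []
    for site in SITE_ORDER:
        r = results.get(site)
        rows.append({
            "site": site,
            "brightness": r.brightness if r else np.nan,
            "corrected_rate": r.corrected_rate if r else np.nan,
            "N": r.N_used if r else np.nan,
            "qc_background_clipped": bool(r.background_clipped) if r else False,
            "missing": r is None,
        })
    extra = set(results) - set(SITE_ORDER)
    if extra:
        raise ValueError(f"unknown site labels: {sorted(extra)}")
    return pd.DataFrame(rows)
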