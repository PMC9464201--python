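"""Temporal autocorrelation flow metric.

Moving blood speckle decorrelates a pixel's intensity time series: the
faster the flow, the sooner the autocorrelation

    R(n) = E[(p(t) - mu) (p(t + n) - mu)] / sigma^2

drops. Two normalization conventions are supported for mu and sigma:

``per-pixel-temporal``
    mu, sigma are the pixel's own temporal mean and SD, so R(0) = 1 exactly
    and the curve is an ordinary correlation (the default).
``segment-spatial``
    mu, sigma are computed from (or supplied for) the segmented region as a
    whole, matching the wording of a segment-level normalization; R(0) is
    then sigma_pixel^2 / sigma_segment^2 rather than 1.

The scalar flow proxy is the median over a region of interest of the
reciprocal decorrelation lag 1/n*, where n* is the smallest lag with
R(n) < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSignalError, ParameterError
from .video_io import VideoClip

__all__ = [
    "PixelTimeSeries",
    "AutocorrelationCurve",
    "FlowEstimate",
    "autocorrelation",
    "autocorrelation_curve",
    "flow_metric",
    "CONVENTIONS",
]

CONVENTIONS = ("per-pixel-temporal", "segment-spatial")


@dataclass(frozen=True)
class PixelTimeSeries:
    """Intensity of one pixel (i, j) over T >= 2 frames."""

    values: np.ndarray
    pixel: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ParameterError("a pixel time series needs at least 2 frames")


@dataclass(frozen=True)
class AutocorrelationCurve:
    """R(n) for lags 0..N with the normalization actually used."""

    lags: np.ndarray
    values: np.ndarray
    normalization_mu: float
    normalization_sigma: float
    convention_tag: str


@dataclass(frozen=True)
class FlowEstimate:
    """Decorrelation-lag summary over an ROI.

    ``lag_map`` holds each ROI pixel's n* (NaN where R never fell below the
    threshold or the pixel was degenerate); ``flow_proxy`` is the median of
    1/n* in frames^-1, or NaN when no pixel decorrelates.
    """

    roi_size: int
    n_excluded: int
    median_lag: float
    flow_proxy: float
    lag_map: np.ndarray = field(repr=False)
    convention_tag: str = "per-pixel-temporal"
    threshold: float = 0.5

    @property
    def no_decorrelation(self) -> bool:
        return not np.isfinite(self.flow_proxy)


def _norm_constants(series: np.ndarray, convention: str,
                    mu: float | None, sigma: float | None) -> tuple[float, float]:
    """(mu, sigma^2) under the chosen convention.

    The per-pixel variance is computed as the mean centred square — the same
    expression as the lag-0 product — so R(0) is exactly 1.
    """
    if convention not in CONVENTIONS:
        raise ParameterError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    if convention == "per-pixel-temporal":
        mu = float(series.mean())
        centred = series - mu
        sigma2 = float((centred * centred).mean())
    else:
        if mu is None or sigma is None:
            raise ParameterError("segment-spatial convention needs mu and sigma "
                                 "of the segmented region")
        sigma2 = float(sigma) ** 2
    if sigma2 <= 0:
        raise DegenerateSignalError("sigma = 0: constant signal, R(n) undefined")
    return float(mu), sigma2


def autocorrelation(series: PixelTimeSeries | np.ndarray, n: int,
                    convention: str = "per-pixel-temporal",
                    mu: float | None = None, sigma: float | None = None) -> float:
    """R(n) for one pixel series at a single lag ``n``.

    The expectation is the mean over the T - n valid frame pairs. Under the
    per-pixel-temporal convention sigma^2 is the series' own (population)
    variance, which makes R(0) exactly 1.
    """
    values = series.values if isinstance(series, PixelTimeSeries) else \
        np.asarray(series, dtype=np.float64)
    t_len = values.size
    if not 0 <= n < t_len:
        raise ParameterError(f"lag {n} outside [0, {t_len})")
    mu, sigma2 = _norm_constants(values, convention, mu, sigma)
    c = values - mu
    prod = c[: t_len - n] * c[n:] if n else c * c
    return float(prod.mean() / sigma2)


def autocorrelation_curve(series: PixelTimeSeries | np.ndarray, max_lag: int,
                          convention: str = "per-pixel-temporal",
                          mu: float | None = None,
                          sigma: float | None = None) -> AutocorrelationCurve:
    """R(n) for all lags 0..max_lag."""
    values = series.values if isinstance(series, PixelTimeSeries) else \
        np.asarray(series, dtype=np.float64)
    mu_, sigma2 = _norm_constants(values, convention, mu, sigma)
    t_len = values.size
    c = values - mu_
    lags = np.arange(min(max_lag, t_len - 1) + 1)
    vals = np.array([float(((c[: t_len - n] * c[n:]) if n else c * c).mean()
                           / sigma2) for n in lags])
    return AutocorrelationCurve(lags=lags, values=vals, normalization_mu=mu_,
                                normalization_sigma=float(np.sqrt(sigma2)),
                                convention_tag=convention)


def flow_metric(clip: VideoClip, roi: np.ndarray, max_lag: int = 15,
                threshold: float = 0.5,
                convention: str = "per-pixel-temporal") -> FlowEstimate:
    """Decorrelation-lag flow proxy over a pixel mask.

    For every ROI pixel the temporal autocorrelation curve is computed and
    n* is the smallest lag >= 1 with R(n*) < ``threshold``. Pixels that
    never decorrelate within ``max_lag`` — including constant (degenerate)
    pixels — are excluded and counted. When every pixel is excluded the
    result carries ``no_decorrelation`` instead of raising.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != clip.frame_shape:
        raise ParameterError(f"roi shape {roi.shape} != frame shape {clip.frame_shape}")
    if not roi.any():
        raise ParameterError("empty ROI")
    if clip.n_frames <= max_lag:
        raise ParameterError(f"clip length {clip.n_frames} must exceed max_lag {max_lag}")

    series = clip.frames[:, roi]  # (T, n_pixels)
    t_len = series.shape[0]
    mu = series.mean(axis=0)
    sigma2 = series.var(axis=0)
    if convention == "segment-spatial":
        mu_seg = float(series.mean())
        sigma2_seg = float(series.var())
        centred = series - mu_seg
        norm = np.full(series.shape[1],
                       sigma2_seg if sigma2_seg > 0 else np.nan)
    elif convention == "per-pixel-temporal":
        centred = series - mu
        norm = sigma2
    else:
        raise ParameterError(f"unknown convention {convention!r}")

    lag_star = np.full(series.shape[1], np.nan)
    undecided = norm > 0
    for n in range(1, max_lag + 1):
        r_n = (centred[: t_len - n] * centred[n:]).mean(axis=0) / np.where(
            norm > 0, norm, np.nan)
        hit = undecided & (r_n < threshold)
        lag_star[hit] = n
        undecided &= ~hit

    finite = np.isfinite(lag_star)
    n_excluded = int((~finite).sum())
    if finite.any():
        median_lag = float(np.median(lag_star[finite]))
        proxy = float(np.median(1.0 / lag_star[finite]))
    else:
        median_lag = float("nan")
        proxy = float("nan")

    lag_map = np.full(clip.frame_shape, np.nan)
    lag_map[roi] = lag_star
    return FlowEstimate(roi_size=int(roi.sum()), n_excluded=n_excluded,
                        median_lag=median_lag, flow_proxy=proxy,
                        lag_map=lag_map, convention_tag=convention,
                        threshold=threshold)
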