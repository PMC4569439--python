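"""Intensity habitat segmentation.

Each channel's ROI intensities are min-max scaled to 256 gray levels and
modeled as a two-component univariate Gaussian mixture. The low/high
habitat threshold is the average of the two fitted component means; pixels
at or below the threshold form the low habitat, pixels above it the high
habitat. The four masks (T1 low/high, T2 low/high) partition the ROI per
channel while the T1 and T2 habitats may overlap spatially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from scipy.special import logsumexp

_SD_FLOOR = 1e-3  # gray levels; prevents component collapse on ties


@dataclass
class GaussianMixtureFit:
    """Two-component 1-D Gaussian mixture, means sorted ascending."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class HabitatMaskSet:
    """Four binary habitat masks over one ROI plus the per-channel thresholds."""

    t1_low: np.ndarray
    t1_high: np.ndarray
    t2_low: np.ndarray
    t2_high: np.ndarray
    thresholds: dict

    def roi(self) -> np.ndarray:
        return self.t1_low | self.t1_high

    def as_dict(self) -> dict:
        return {"T1low": self.t1_low, "T1high": self.t1_high,
                "T2low": self.t2_low, "T2high": self.t2_high}


def scale_intensities(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly rescale within-ROI intensities to integer gray levels 0..255.

    Pixels outside the mask are set to 0 and carry no meaning downstream.
    Raises on a constant ROI (the linear map is undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(image, dtype=float)[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the ROI")
    mn, mx = vals.min(), vals.max()
    if mx == mn:
        raise ValueError("degenerate intensity range: constant ROI intensity")
    out = np.zeros(np.asarray(image).shape, dtype=np.int16)
    out[mask] = np.rint((vals - mn) / (mx - mn) * 255.0).astype(np.int16)
    return out


def fit_two_component_gmm(values, seed: int = 0) -> GaussianMixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialization splits the data at the median (deterministic; ``seed``
    kept for API stability only). Convergence when the log-likelihood
    improves by less than 1e-6, capped at 500 iterations.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 20:
        raise ValueError(f"need >= 20 values to fit the mixture (got {x.size})")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values to fit the mixture")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum(np.array([lo.std(), hi.std()]), _SD_FLOOR)
    w = np.array([lo.size, hi.size], dtype=float) / x.size

    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, 501):
        # E step
        logp = (np.log(w)[:, None]
                + norm.logpdf(x[None, :], mu[:, None], sd[:, None]))
        tot = logsumexp(logp, axis=0)
        new_loglik = float(tot.sum())
        resp = np.exp(logp - tot[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), _SD_FLOOR)
        w = nk / x.size
        if new_loglik - loglik < 1e-6:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(mu)
    return GaussianMixtureFit(means=mu[order], sds=sd[order],
                              weights=w[order], loglik=loglik,
                              n_iter=n_iter, converged=converged)


def habitat_threshold(fit: GaussianMixtureFit) -> float:
    """Average of the two component means."""
    return float((fit.means[0] + fit.means[1]) / 2.0)


def assign_habitats(pair, seed: int = 0) -> HabitatMaskSet:
    """Scale, fit and threshold both channels of one tumor slice pair.

    A pixel with scaled intensity <= threshold goes to the low habitat,
    > threshold to the high habitat (ties resolve to low).
    """
    mask = np.asarray(pair.mask, dtype=bool)
    masks = {}
    thresholds = {}
    for name, image in (("t1", pair.t1), ("t2", pair.t2)):
        scaled = scale_intensities(image, mask)
        fit = fit_two_component_gmm(scaled[mask], seed=seed)
        thr = habitat_threshold(fit)
        masks[name + "_low"] = mask & (scaled <= thr)
        masks[name + "_high"] = mask & (scaled > thr)
        thresholds[name] = thr
    return HabitatMaskSet(t1_low=masks["t1_low"], t1_high=masks["t1_high"],
                          t2_low=masks["t2_low"], t2_high=masks["t2_high"],
                          thresholds=thresholds)
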