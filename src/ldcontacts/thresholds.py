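"""Automatic histogram thresholding (Otsu, Yen, Huang) on 256-bin histograms.

All three methods follow the ImageJ Auto_Threshold conventions: they operate
on the 256-bin histogram of an 8-bit(-converted) plane, return a level ``t``
in [0, 255] such that *foreground is strictly greater than* ``t``, and break
ties by the smallest optimising level. Higher-depth planes are 8-bit converted
before their histogram is taken.
"""

from __future__ import annotations

import math

import numpy as np

from .io import to_8bit


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated bins; no split exists."""


def histogram256(plane8: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit plane."""
    return np.bincount(np.asarray(plane8, dtype=np.uint8).ravel(), minlength=256)


def _check(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,) or np.any(hist < 0):
        raise ValueError("expected a 256-bin nonnegative histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("fewer than two populated bins")
    return hist


def otsu_threshold(hist: np.ndarray) -> int:
    """Level maximising the between-class variance of the split {<=t, >t}."""
    hist = _check(hist)
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)                      # class probability of {<=t}
    mu = np.cumsum(p * np.arange(256))         # first moment up to t
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))             # argmax returns the smallest maximiser


def yen_threshold(hist: np.ndarray) -> int:
    """Level maximising Yen's maximum-correlation criterion.

    Criterion (per threshold t, with p the normalised histogram,
    P1 = sum p[:t+1], P1sq = sum p[:t+1]^2, P2sq the complement):
    ``-log(P1sq * P2sq) + 2 log(P1 (1 - P1))``, terms dropped when their
    argument is non-positive.
    """
    hist = _check(hist)
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P1sq = np.cumsum(p * p)
    P2sq = P1sq[-1] - P1sq
    term1 = np.where(P1sq * P2sq > 0, np.log(np.maximum(P1sq * P2sq, 1e-300)), 0.0)
    arg2 = P1 * (1.0 - P1)
    term2 = np.where(arg2 > 0, np.log(np.maximum(arg2, 1e-300)), 0.0)
    crit = -term1 + 2.0 * term2
    return int(np.argmax(crit))


def huang_threshold(hist: np.ndarray) -> int:
    """Level minimising Huang & Wang's fuzzy Shannon entropy.

    For a split at t, each bin's membership to its class is
    ``mu = 1 / (1 + |g - m| / C)`` where ``m`` is the class mean intensity
    rounded to the nearest integer and ``C`` the populated histogram range;
    the score is ``sum counts * (-mu log mu - (1-mu) log(1-mu))``. The
    smallest minimiser is returned, and only splits with both classes
    populated are considered.
    """
    hist = _check(hist)
    nz = np.nonzero(hist)[0]
    first, last = int(nz[0]), int(nz[-1])
    C = float(last - first)
    g = np.arange(256, dtype=np.float64)
    W = np.cumsum(g * hist)
    S = np.cumsum(hist)

    # entropy of membership as a function of |g - m|, precomputed
    d = np.arange(256, dtype=np.float64)
    mu = 1.0 / (1.0 + d / C)
    with np.errstate(divide="ignore", invalid="ignore"):
        smu = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
    smu[mu >= 1.0] = 0.0  # d == 0: membership 1, zero entropy

    best_t, best_ent = -1, np.inf
    for t in range(first, last):  # both classes populated on [first, last]
        m0 = int(round(W[t] / S[t]))
        m1 = int(round((W[last] - W[t]) / (S[last] - S[t])))
        lo = np.abs(np.arange(0, t + 1) - m0)
        hi = np.abs(np.arange(t + 1, 256) - m1)
        # correctly-rounded summation: the score is order-independent, so
        # near-ties resolve identically however the terms are accumulated
        ent = math.fsum(np.concatenate([smu[lo] * hist[: t + 1], smu[hi] * hist[t + 1 :]]))
        if ent < best_ent:
            best_ent, best_t = ent, t
    return best_t


_METHODS = {
    "otsu": otsu_threshold,
    "yen": yen_threshold,
    "huang": huang_threshold,
}


def threshold_by_name(hist: np.ndarray, method: str) -> int:
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}; choose from {sorted(_METHODS)}")
    return fn(hist)


def apply_threshold(plane: np.ndarray, level: int, bit_depth: int = 8) -> np.ndarray:
    """Boolean mask of pixels whose 8-bit intensity is strictly above ``level``."""
    if not 0 <= level <= 255:
        raise ValueError(f"level must be in [0, 255], got {level}")
    return to_8bit(plane, bit_depth) > level


def auto_mask(plane: np.ndarray, method: str, bit_depth: int = 8):
    """8-bit convert, auto-threshold and binarise a plane.

    Returns ``(mask, level)``. A degenerate histogram yields an empty mask
    and level 255 (nothing is strictly above it).
    """
    import logging

    plane8 = to_8bit(plane, bit_depth)
    try:
        level = threshold_by_name(histogram256(plane8), method)
    except DegenerateHistogramError:
        logging.getLogger("ldcontacts").warning(
            "degenerate histogram for %s threshold; returning empty mask", method
        )
        return np.zeros(plane8.shape, dtype=bool), 255
    return plane8 > level, level
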