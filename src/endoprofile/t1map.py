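"""Variable-flip-angle T1 relaxometry for spoiled gradient-echo series.

The steady-state magnitude of an ideally spoiled gradient-echo acquisition is

    S(alpha) = M0 * sin(alpha) * (1 - E) / (1 - E * cos(alpha)),
    E = exp(-TR / T1),

so sampling S at several flip angles determines (M0, T1).  The classic
linearisation S/sin(alpha) = E * S/tan(alpha) + M0 * (1 - E) turns the fit
into a straight line whose slope is E; a nonlinear least-squares refinement
of the exact model, started from the linear estimate, is applied on top by
default.  Failed fits (no signal, non-physical slope, T1 out of range) are
marked undefined and propagate as missing values, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import VfaSeries

__all__ = [
    "spgr_signal",
    "fit_t1_pixel",
    "fit_t1_map",
    "T1FitResult",
    "T1Map",
    "T1_MAX_MS_DEFAULT",
]

T1_MAX_MS_DEFAULT = 10_000.0

# Coded reasons for undefined pixels.
REASON_OK = ""
REASON_NO_SIGNAL = "no signal"
REASON_NONPHYSICAL = "non-physical slope"
REASON_OUT_OF_RANGE = "T1 out of range"


def spgr_signal(m0, t1_ms, tr_ms: float, alpha_deg) -> np.ndarray:
    """Steady-state spoiled gradient-echo magnitude signal.

    Vectorised over any broadcastable combination of ``m0``, ``t1_ms`` and
    ``alpha_deg``.  Returns 0 for zero flip angle or zero ``m0``.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 90):
        raise ValueError("alpha_deg must lie in [0, 90]")
    e1 = np.exp(-tr_ms / t1)
    a = np.deg2rad(alpha)
    s = np.asarray(m0, dtype=float) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return s


@dataclass(frozen=True)
class T1FitResult:
    """Single-pixel VFA fit: estimates are NaN when the fit is undefined."""

    t1_ms: float
    m0: float
    fit_quality: float
    reason: str = REASON_OK

    @property
    def defined(self) -> bool:
        return self.reason == REASON_OK


def _r_squared(signals: np.ndarray, predicted: np.ndarray) -> float:
    resid = signals - predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((signals - signals.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def _linear_fit(
    signals: np.ndarray, sin_a: np.ndarray, tan_a: np.ndarray, tr_ms: float
) -> Tuple[float, float, str]:
    """DESPOT1-style linearised fit; returns (t1_ms, m0, reason)."""
    y = signals / sin_a
    x = signals / tan_a
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        return np.nan, np.nan, REASON_NO_SIGNAL
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    if not (0.0 < slope < 1.0):
        return np.nan, np.nan, REASON_NONPHYSICAL
    t1 = -tr_ms / np.log(slope)
    m0 = intercept / (1.0 - slope)
    return float(t1), float(m0), REASON_OK


def fit_t1_pixel(
    signals,
    flip_angles_deg,
    tr_ms: float,
    method: str = "nonlinear",
    t1_max_ms: float = T1_MAX_MS_DEFAULT,
) -> T1FitResult:
    """Estimate (T1, M0) for one pixel from its per-angle magnitudes.

    ``method='linear'`` uses the linearised solution only; ``'nonlinear'``
    refines it by least squares on the exact SPGR model.  Estimates outside
    ``(0, t1_max_ms]``, all-zero signal vectors, or non-physical slopes
    (implying E outside (0, 1)) yield an undefined result with a coded
    reason.
    """
    if method not in ("linear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    s = np.asarray(signals, dtype=float)
    angles = np.asarray(flip_angles_deg, dtype=float)
    if s.shape != angles.shape:
        raise ValueError(
            f"{s.size} signals for {angles.size} flip angles (lengths must match)"
        )
    if angles.size < 2:
        raise ValueError("at least two flip angles are required")
    if np.unique(angles).size < 2:
        raise ValueError("degenerate design: all flip angles equal")
    if np.all(s == 0):
        return T1FitResult(np.nan, np.nan, 0.0, REASON_NO_SIGNAL)

    a = np.deg2rad(angles)
    sin_a, tan_a = np.sin(a), np.tan(a)
    t1, m0, reason = _linear_fit(s, sin_a, tan_a, tr_ms)
    if reason != REASON_OK:
        return T1FitResult(np.nan, np.nan, 0.0, reason)

    if method == "nonlinear":

        def resid(p):
            return spgr_signal(p[0], p[1], tr_ms, angles) - s

        sol = least_squares(
            resid,
            x0=[max(m0, 1e-9), float(np.clip(t1, 1e-3, t1_max_ms))],
            bounds=([0.0, 1e-3], [np.inf, 10.0 * t1_max_ms]),
        )
        m0, t1 = float(sol.x[0]), float(sol.x[1])

    if not (0.0 < t1 <= t1_max_ms):
        return T1FitResult(np.nan, np.nan, 0.0, REASON_OUT_OF_RANGE)
    quality = _r_squared(s, spgr_signal(m0, t1, tr_ms, angles))
    return T1FitResult(t1, m0, quality, REASON_OK)


@dataclass
class T1Map:
    """Per-pixel T1 estimates; NaN marks pixels where the fit is undefined.

    ``mask`` records which pixels were attempted; ``n_failed`` counts the
    attempted pixels whose fit was rejected.  Undefined pixels are excluded
    from all downstream statistics.
    """

    t1_ms: np.ndarray
    m0: np.ndarray
    fit_quality: np.ndarray
    mask: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        defined = np.isfinite(self.t1_ms)
        if np.any(self.t1_ms[defined] <= 0):
            raise ValueError("defined T1 estimates must be positive")
        q = self.fit_quality[defined]
        if q.size and (np.nanmin(q) < 0 or np.nanmax(q) > 1):
            raise ValueError("fit_quality must lie in [0, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.t1_ms)

    @property
    def failed_fraction(self) -> float:
        attempted = int(self.mask.sum())
        return self.n_failed / attempted if attempted else 0.0


def fit_t1_map(
    series: "VfaSeries",
    mask: Optional[np.ndarray] = None,
    method: str = "nonlinear",
    t1_max_ms: float = T1_MAX_MS_DEFAULT,
) -> T1Map:
    """Fit the SPGR model pixel by pixel under a mask.

    The linearised fit is vectorised over all masked pixels; the nonlinear
    refinement then revisits each defined pixel.  Deterministic for fixed
    input.
    """
    vols = series.volumes
    shape = vols.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {shape}")
    if not mask.any():
        raise ValueError("empty mask: no pixels to fit")

    angles = np.asarray(series.flip_angles_deg, dtype=float)
    tr = series.protocol.tr_ms
    a = np.deg2rad(angles)
    sin_a, tan_a = np.sin(a), np.tan(a)

    sig = vols[:, mask].astype(float)  # (n_angles, n_pix)
    y = sig / sin_a[:, None]
    x = sig / tan_a[:, None]
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = np.sum((x - xm) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.sum((x - xm) * (y - ym), axis=0) / sxx
        intercept = ym - slope * xm
        t1 = -tr / np.log(slope)
        m0 = intercept / (1.0 - slope)

    no_signal = np.all(sig == 0, axis=0) | (sxx == 0)
    nonphys = ~no_signal & ~((slope > 0) & (slope < 1))
    bad = no_signal | nonphys
    t1[bad] = np.nan
    m0[bad] = np.nan

    if method == "nonlinear":
        good = np.flatnonzero(~bad)
        for j in good:
            res = fit_t1_pixel(sig[:, j], angles, tr, "nonlinear", t1_max_ms)
            t1[j], m0[j] = res.t1_ms, res.m0
    out_of_range = ~bad & ~((t1 > 0) & (t1 <= t1_max_ms))
    t1[out_of_range] = np.nan
    m0[out_of_range] = np.nan
    bad = bad | out_of_range

    defined = ~bad
    quality = np.zeros(t1.shape)
    if defined.any():
        # per-pixel R^2 against the exact model
        pred = spgr_signal(
            m0[defined][None, :], t1[defined][None, :], tr, angles[:, None]
        )
        obs = sig[:, defined]
        ss_res = np.sum((obs - pred) ** 2, axis=0)
        ss_tot = np.sum((obs - obs.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        r2 = np.where(ss_tot == 0, np.where(ss_res == 0, 1.0, 0.0), r2)
        quality[defined] = np.clip(r2, 0.0, 1.0)

    t1_map = np.full(shape, np.nan)
    m0_map = np.full(shape, np.nan)
    q_map = np.full(shape, np.nan)
    t1_map[mask] = t1
    m0_map[mask] = m0
    q_map[mask] = quality
    return T1Map(
        t1_ms=t1_map,
        m0=m0_map,
        fit_quality=q_map,
        mask=mask,
        n_failed=int(bad.sum()),
    )
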