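"""Patlak graphical analysis for irreversible tracers.

For an irreversibly trapped tracer the transformed coordinates

    x(t) = ∫₀ᵗ Cp(s) ds / Cp(t)      ("normalized time", min)
    y(t) = Ct(t) / Cp(t)

become linear after an equilibration time t*, with slope Ki (net influx,
ml·g⁻¹·min⁻¹) and intercept V (apparent distribution volume, ml·g⁻¹).
The input function Cp may be a sampled curve (IDIF) — the running integral
is then a cumulative trapezoid from t=0 — or an analytic Feng model /
scaled PBIF, in which case the integral is exact.  The analytic route is
what makes abbreviated protocols work: the early part of ∫Cp comes from
the population shape rather than from early images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson

from .input_function import FengParams, SampledCurve, feng_cumint, feng_eval
from .pbif import PopulationInputFunction, ScaledPBIF

__all__ = ["PatlakPoints", "PatlakResult", "patlak_transform", "patlak_fit", "roi_patlak"]

logger = logging.getLogger(__name__)

InputFunction = SampledCurve | FengParams | ScaledPBIF | PopulationInputFunction


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak-transformed points with their original frame mid-times."""

    t: np.ndarray  # frame mid-times, min
    x: np.ndarray  # normalized time, min
    y: np.ndarray  # tissue-to-plasma ratio


@dataclass(frozen=True)
class PatlakResult:
    """One Patlak line fit: slope Ki, intercept V, goodness of fit."""

    ki: float
    v: float
    r_squared: float
    t_star: float
    n_points: int
    residuals: np.ndarray

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("a Patlak fit needs at least 2 points")


def _resolve_input(cp: InputFunction, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Cp(t), ∫₀ᵗCp) at the requested times for any input-function type."""
    if isinstance(cp, ScaledPBIF):
        cp = cp.as_feng()
    elif isinstance(cp, PopulationInputFunction):
        cp = cp.params
    if isinstance(cp, FengParams):
        return np.asarray(feng_eval(cp, times)), np.asarray(feng_cumint(cp, times))
    if isinstance(cp, SampledCurve):
        mids = cp.mid
        if mids.shape != times.shape or not np.allclose(mids, times, rtol=0, atol=1e-9):
            raise ValueError(
                "sampled input function must share the tissue curve's frame schedule"
            )
        # Running integral from t=0, extending the first value back to time
        # zero.  A cumulative Simpson rule is used instead of a trapezoid:
        # the trapezoid's O(h^2) error on the sharp input peak leaves a
        # persistent ~0.1% excess in the late integral, which would bleed a
        # systematic error of the same order into every Patlak slope driven
        # by a sampled input function.
        tt = np.concatenate(([0.0], mids))
        vv = np.concatenate(([cp.value[0]], cp.value))
        if tt.size >= 3:
            integral = cumulative_simpson(vv, x=tt, initial=0.0)[1:]
        else:
            integral = np.cumsum(0.5 * (vv[1:] + vv[:-1]) * np.diff(tt))
        return cp.value.copy(), integral
    raise TypeError(f"unsupported input-function type: {type(cp).__name__}")


def patlak_transform(ct: SampledCurve, cp: InputFunction) -> PatlakPoints:
    """Transform a tissue curve against an input function into Patlak coordinates.

    Frames with nonpositive Cp are excluded (logged); if every frame is
    excluded a ValueError is raised.
    """
    times = ct.mid
    cp_vals, cp_int = _resolve_input(cp, times)
    keep = cp_vals > 0
    if not np.any(keep):
        raise ValueError("input function is nonpositive at every frame mid-time")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "patlak_transform: excluded %d frame(s) with nonpositive input function",
            n_dropped,
        )
    t = times[keep]
    return PatlakPoints(t=t, x=cp_int[keep] / cp_vals[keep], y=ct.value[keep] / cp_vals[keep])


def patlak_fit(points: PatlakPoints, t_star: float, weights=None) -> PatlakResult:
    """Ordinary least-squares Patlak line through points with mid-time >= t_star.

    ``weights`` (optional, e.g. frame durations) switches to weighted least
    squares; the default matches the conventional unweighted Patlak fit.
    """
    sel = points.t >= t_star
    n = int(sel.sum())
    if n < 2:
        raise ValueError(
            f"fewer than 2 points at or after t*={t_star} min "
            f"(available mid-times span [{points.t.min():.3g}, {points.t.max():.3g}] min)"
        )
    x = points.x[sel]
    y = points.y[sel]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)[sel]
    wsum = w.sum()
    xm = np.dot(w, x) / wsum
    ym = np.dot(w, y) / wsum
    xc = x - xm
    yc = y - ym
    sxx = np.dot(w * xc, xc)
    if sxx <= 0:
        raise ValueError("degenerate Patlak abscissa: no spread in normalized time")
    slope = np.dot(w * xc, yc) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = np.dot(w * resid, resid)
    ss_tot = np.dot(w * yc, yc)
    r2 = 1.0 if ss_tot == 0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    return PatlakResult(
        ki=float(slope),
        v=float(intercept),
        r_squared=r2,
        t_star=float(t_star),
        n_points=n,
        residuals=resid,
    )


def roi_patlak(
    subject,
    input_fn: InputFunction,
    t_star: float,
    labels: list[str] | None = None,
    weights=None,
) -> dict[str, PatlakResult]:
    """Patlak transform + fit for each labeled ROI curve of a subject."""
    available = subject.labels
    labels = available if labels is None else list(labels)
    missing = [lab for lab in labels if lab not in available]
    if missing:
        raise KeyError(f"labels not present in subject {subject.subject_id}: {missing}")
    out = {}
    for lab in labels:
        points = patlak_transform(subject.tac(lab), input_fn)
        out[lab] = patlak_fit(points, t_star, weights=weights)
    return out
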