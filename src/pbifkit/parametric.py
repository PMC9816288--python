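"""Voxel-wise Patlak parametric maps and image-fidelity metrics.

The voxel-wise analysis is the indirect (image-space) analogue of direct
parametric reconstruction: every masked voxel's time series is Patlak
transformed against a shared input function and fitted with the same
ordinary least squares as the ROI-level fit.  Map agreement is quantified
with the fidelity metrics conventional for parametric images: percent
relative change (RC), structural similarity (SSIM) and peak signal-to-noise
ratio (PSNR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .patlak import InputFunction, _resolve_input
from .synthetic import FrameSchedule

__all__ = ["ParametricImage", "ImageMetrics", "voxelwise_patlak", "image_metrics"]

logger = logging.getLogger(__name__)

#: voxels with |ref| below this fraction of the masked max are excluded from RC
RC_REFERENCE_FLOOR = 0.01


@dataclass
class ParametricImage:
    """Voxel-wise Patlak results: Ki and intercept maps plus a validity mask."""

    ki_map: np.ndarray
    v_map: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ki_map.shape == self.v_map.shape == self.mask.shape):
            raise ValueError("ki_map, v_map and mask must share one shape")

    @property
    def n_failed(self) -> int:
        return int(self.provenance.get("n_failed_voxels", 0))


@dataclass(frozen=True)
class ImageMetrics:
    """Fidelity of a test parametric map against a reference map."""

    mean_rc: float  # percent
    sd_rc: float
    mean_abs_rc: float
    sd_abs_rc: float
    ssim: float
    psnr: float  # dB; +inf for identical images
    n_rc_voxels: int = 0
    rc_floor: float = RC_REFERENCE_FLOOR

    def to_dict(self) -> dict:
        d = {
            "mean_rc": self.mean_rc,
            "sd_rc": self.sd_rc,
            "mean_abs_rc": self.mean_abs_rc,
            "sd_abs_rc": self.sd_abs_rc,
            "ssim": self.ssim,
            "psnr": "inf" if np.isinf(self.psnr) else self.psnr,
            "n_rc_voxels": self.n_rc_voxels,
            "rc_floor": self.rc_floor,
        }
        return d


def voxelwise_patlak(
    volume: np.ndarray,
    schedule: FrameSchedule,
    input_fn: InputFunction,
    t_star: float,
    mask: np.ndarray | None = None,
) -> ParametricImage:
    """Patlak Ki/V maps over a 4D volume (x, y, z, frame).

    Applies the same transform and OLS line as the ROI-level fit to every
    masked voxel (vectorized; the Patlak abscissa is shared because the
    input function is).  Voxels whose fit is undefined (non-finite series)
    are set NaN and counted in the provenance QC field.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {volume.shape}")
    if volume.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"frame axis ({volume.shape[-1]}) does not match the schedule "
            f"({schedule.n_frames} frames)"
        )
    dims = volume.shape[:3]
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dims:
        raise ValueError(f"mask shape {mask.shape} does not match volume {dims}")

    times = schedule.mid_min
    cp_vals, cp_int = _resolve_input(input_fn, times)
    keep = cp_vals > 0
    if (~keep).any():
        logger.warning(
            "voxelwise_patlak: excluded %d frame(s) with nonpositive input function",
            int((~keep).sum()),
        )
    sel = keep & (times >= t_star)
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 usable frames at or after t*={t_star} min")
    x = cp_int[sel] / cp_vals[sel]
    n = x.size

    series = volume[mask][:, sel]  # (n_voxels, n_points)
    y = series / cp_vals[sel]
    finite = np.all(np.isfinite(y), axis=1)

    w = np.ones(n)
    wsum = w.sum()
    xm = np.dot(w, x) / wsum
    xc = x - xm
    sxx = np.dot(w * xc, xc)
    ym = (y @ w) / wsum
    yc = y - ym[:, None]
    slope = (yc @ (w * xc)) / sxx
    intercept = ym - slope * xm
    slope[~finite] = np.nan
    intercept[~finite] = np.nan

    ki_map = np.full(dims, np.nan)
    v_map = np.full(dims, np.nan)
    ki_map[mask] = slope
    v_map[mask] = intercept
    return ParametricImage(
        ki_map=ki_map,
        v_map=v_map,
        mask=mask,
        provenance={
            "t_star": float(t_star),
            "input_fn": getattr(input_fn, "label", type(input_fn).__name__),
            "n_points": int(n),
            "n_failed_voxels": int((~finite).sum()),
            "schedule_hash": hash(tuple(np.round(schedule.start_s, 6))),
        },
    )


def _as_map(img) -> np.ndarray:
    return img.ki_map if isinstance(img, ParametricImage) else np.asarray(img, dtype=float)


def image_metrics(test, ref, mask: np.ndarray, data_range: float | None = None) -> ImageMetrics:
    """RC / SSIM / PSNR of a test Ki map against a reference Ki map.

    RC_v = 100*(test_v - ref_v)/ref_v over masked voxels whose |ref| is at
    least 1% of the masked max (division guard); mean±SD of RC and |RC| are
    reported with the sample SD.  SSIM uses a 7³ window, constants
    K1=0.01/K2=0.03, and data range = masked (max - min) of the reference
    unless overridden; the SSIM map is averaged within the mask.  PSNR uses
    range = masked max of the reference; identical images give +inf.
    Voxels outside the mask are zeroed in both images before SSIM.
    """
    test = _as_map(test)
    ref = _as_map(ref)
    mask = np.asarray(mask, dtype=bool)
    if test.shape != ref.shape or mask.shape != ref.shape:
        raise ValueError("test, ref and mask must share one shape")
    if not mask.any():
        raise ValueError("mask is empty")

    ref_m = ref[mask]
    test_m = test[mask]
    floor = RC_REFERENCE_FLOOR * np.nanmax(np.abs(ref_m))
    rc_sel = np.abs(ref_m) >= floor
    rc = 100.0 * (test_m[rc_sel] - ref_m[rc_sel]) / ref_m[rc_sel]
    if rc.size == 0:
        raise ValueError("no voxels above the RC reference floor")
    sd = float(np.std(rc, ddof=1)) if rc.size > 1 else float("nan")
    sd_abs = float(np.std(np.abs(rc), ddof=1)) if rc.size > 1 else float("nan")

    ref0 = np.where(mask, np.nan_to_num(ref), 0.0)
    test0 = np.where(mask, np.nan_to_num(test), 0.0)
    rng_ssim = float(np.nanmax(ref_m) - np.nanmin(ref_m)) if data_range is None else data_range
    if rng_ssim <= 0:
        raise ValueError("reference has zero data range within the mask")
    _, ssim_map = structural_similarity(
        ref0, test0, win_size=7, data_range=rng_ssim, K1=0.01, K2=0.03, full=True
    )
    ssim = float(np.mean(ssim_map[mask]))

    mse = float(np.mean((test_m - ref_m) ** 2))
    peak = float(np.nanmax(ref_m))
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(peak**2 / mse)
    return ImageMetrics(
        mean_rc=float(np.mean(rc)),
        sd_rc=sd,
        mean_abs_rc=float(np.mean(np.abs(rc))),
        sd_abs_rc=sd_abs,
        ssim=ssim,
        psnr=psnr,
        n_rc_voxels=int(rc.size),
    )
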