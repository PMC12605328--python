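"""No-reference image-quality metrics for 3D T1-weighted volumes.

Implements the small IQM battery used as decision-tree predictors for
acquisition-sequence QC — contrast-to-noise ratio (CNR), spatial noise
smoothness (per-axis FWHM), and the acquisition field of view along the
left-right (FOVx) and anterior-posterior (FOVy) anatomical axes — plus two
auxiliary metrics: the coefficient of joint variation (CJV) and the
entropy-focus criterion (EFC).

Tissue masks (gray matter, white matter, air background) are inputs; no
segmentation is performed here.  Session-level IQMs are the arithmetic
means of the per-scan values across the back-to-back repeat scans of a
session, with the (necessarily identical) acquisition geometry taken from
the scans' headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueStats",
    "IQMRecord",
    "FwhmEstimate",
    "tissue_stats",
    "cnr",
    "cjv",
    "efc",
    "fwhm",
    "fov_from_header",
    "scan_iqm",
    "session_iqm",
]


@dataclass(frozen=True)
class TissueStats:
    """Per-segment intensity mean/variance summaries.

    Variances use the population convention (denominator ``n``) by
    default; see :func:`tissue_stats`.
    """

    mu_gm: float
    mu_wm: float
    var_gm: float
    var_wm: float
    var_air: float
    n_gm: int
    n_wm: int
    n_air: int

    def __post_init__(self) -> None:
        if min(self.var_gm, self.var_wm, self.var_air) < 0:
            raise ValueError("variances must be >= 0")
        if min(self.n_gm, self.n_wm, self.n_air) < 1:
            raise ValueError("segment voxel counts must be >= 1")


@dataclass(frozen=True)
class FwhmEstimate:
    """Per-axis smoothness estimates in mm; undefined axes are NaN."""

    axes_mm: tuple[float, float, float]
    mean_mm: float


@dataclass(frozen=True)
class IQMRecord:
    """IQM values for one scan or one session."""

    cnr: float
    fwhm_mm: float
    fovx_mm: float
    fovy_mm: float
    cjv: float = float("nan")
    efc: float = float("nan")
    fwhm_axes_mm: tuple[float, float, float] = (float("nan"),) * 3

    def as_dict(self) -> dict[str, float]:
        return {
            "cnr": self.cnr,
            "fwhm_mm": self.fwhm_mm,
            "fovx_mm": self.fovx_mm,
            "fovy_mm": self.fovy_mm,
            "cjv": self.cjv,
            "efc": self.efc,
        }


def tissue_stats(
    volume: np.ndarray, masks: Mapping[str, np.ndarray], *, ddof: int = 0
) -> TissueStats:
    """Mean and variance of the intensity in the GM, WM and air segments.

    ``masks`` must provide disjoint boolean arrays under the keys ``gm``,
    ``wm`` and ``air``.  ``ddof=0`` (population variance) is the default;
    segment sizes are normally large enough that the choice is immaterial,
    but it is pinned for reproducibility.
    """
    vol = np.asarray(volume, dtype=float)
    required = ("gm", "wm", "air")
    arrs = {}
    for name in required:
        if name not in masks:
            raise ValueError(f"missing mask for segment {name!r}")
        m = np.asarray(masks[name], dtype=bool)
        if m.shape != vol.shape:
            raise ValueError(f"mask {name!r} shape {m.shape} != volume shape {vol.shape}")
        if not m.any():
            raise ValueError(f"segment {name!r} is empty")
        arrs[name] = m
    overlap = arrs["gm"] & arrs["wm"] | arrs["gm"] & arrs["air"] | arrs["wm"] & arrs["air"]
    if overlap.any():
        raise ValueError("tissue masks must be disjoint")

    def _mv(m: np.ndarray) -> tuple[float, float, int]:
        x = vol[m]
        n = x.size
        var = float(np.var(x, ddof=ddof)) if n > ddof else 0.0
        return float(x.mean()), var, n

    mu_gm, var_gm, n_gm = _mv(arrs["gm"])
    mu_wm, var_wm, n_wm = _mv(arrs["wm"])
    _, var_air, n_air = _mv(arrs["air"])
    return TissueStats(mu_gm, mu_wm, var_gm, var_wm, var_air, n_gm, n_wm, n_air)


def cnr(stats: TissueStats) -> float:
    """Contrast-to-noise ratio.

    ``|mu_GM - mu_WM| / sqrt(var_GM + var_WM + var_Air)`` — the separation
    of the gray and white matter signals relative to the pooled noise
    level.  Larger is better.  Undefined when all three variances are zero.
    """
    total_var = stats.var_gm + stats.var_wm + stats.var_air
    if total_var <= 0:
        raise ValueError("CNR undefined: all segment variances are zero")
    return abs(stats.mu_gm - stats.mu_wm) / float(np.sqrt(total_var))


def cjv(stats: TissueStats, *, variant: str = "sd") -> float:
    """Coefficient of joint variation of the GM/WM intensities.

    The default ``variant="sd"`` is the standard definition
    ``(sigma_GM + sigma_WM) / |mu_GM - mu_WM|``.  ``variant="variance"``
    puts the variances in the numerator instead,
    ``(var_GM + var_WM) / |mu_GM - mu_WM|``; this rendering circulates in
    some method descriptions and is provided for comparability.  Smaller
    is better; undefined for equal tissue means.
    """
    delta = abs(stats.mu_gm - stats.mu_wm)
    if delta == 0:
        raise ValueError("CJV undefined: equal GM and WM means")
    if variant == "sd":
        num = float(np.sqrt(stats.var_gm) + np.sqrt(stats.var_wm))
    elif variant == "variance":
        num = stats.var_gm + stats.var_wm
    else:
        raise ValueError(f"unknown CJV variant {variant!r}")
    return num / delta


def efc(volume: np.ndarray) -> float:
    """Entropy-focus criterion, normalized to [0, 1].

    Shannon entropy of the voxel intensities ``E = -sum_j y_j ln y_j``
    with ``y_j = x_j / sqrt(sum x_j^2)``, divided by the entropy of a
    uniform image with the same voxel count.  A uniform image scores 1
    (maximal entropy), a single-hot image 0.  Sensitive to ghosting and
    blurring; negative intensities are treated as background (clipped to
    zero).
    """
    x = np.asarray(volume, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("EFC requires at least 2 voxels")
    x = np.clip(x, 0.0, None)
    norm = float(np.sqrt(np.sum(x**2)))
    if norm == 0:
        raise ValueError("EFC undefined for an all-zero volume")
    y = x / norm
    nz = y > 0
    entropy = float(-np.sum(y[nz] * np.log(y[nz])))
    n = x.size
    e_max = float(np.sqrt(n) * np.log(np.sqrt(n)))
    return entropy / e_max


def fwhm(
    volume: np.ndarray,
    spacing_mm: Sequence[float],
    mask: np.ndarray | None = None,
) -> FwhmEstimate:
    """Spatial smoothness as a Gaussian-kernel FWHM per axis, in mm.

    Classic first-difference estimator: along each axis,
    ``FWHM = d * sqrt(-2 ln 2 / ln(1 - s2_diff / (2 s2)))`` with ``d`` the
    voxel spacing, ``s2_diff`` the variance of first differences between
    neighbouring in-mask voxels and ``s2`` the in-mask intensity variance.
    For noise produced by smoothing a white field with a Gaussian kernel,
    the estimator returns the kernel FWHM.  An axis rougher than white
    noise (``s2_diff >= 2 s2``) is undefined, reported as NaN and excluded
    from the mean.

    The estimator assumes the in-mask signal is noise-dominated; apply it
    within a homogeneous tissue mask or to a residual image.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    spacing = [float(d) for d in spacing_mm]
    if len(spacing) != 3 or any(d <= 0 for d in spacing):
        raise ValueError("spacing_mm must be 3 positive values")
    m = np.ones(vol.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    s2 = float(np.var(vol[m], ddof=1))
    if s2 == 0:
        raise ValueError("volume is constant within the mask; smoothness undefined")

    axes: list[float] = []
    for ax in range(3):
        d = np.diff(vol, axis=ax)
        pair = np.logical_and(
            np.take(m, range(m.shape[ax] - 1), axis=ax),
            np.take(m, range(1, m.shape[ax]), axis=ax),
        )
        if pair.sum() < 2:
            axes.append(float("nan"))
            continue
        s2_diff = float(np.var(d[pair], ddof=1))
        ratio = s2_diff / (2.0 * s2)
        if ratio >= 1.0 or ratio <= 0.0:
            warnings.warn(
                f"axis {ax}: first-difference variance not below white-noise level; "
                "FWHM undefined for this axis",
                UserWarning,
                stacklevel=2,
            )
            axes.append(float("nan"))
            continue
        axes.append(spacing[ax] * float(np.sqrt(-2.0 * np.log(2.0) / np.log1p(-ratio))))

    finite = [a for a in axes if np.isfinite(a)]
    mean = float(np.mean(finite)) if finite else float("nan")
    return FwhmEstimate(tuple(axes), mean)


def fov_from_header(
    img_or_affine, shape: Sequence[int] | None = None, *, min_cosine: float = 0.6
) -> tuple[float, float]:
    """Field of view along the left-right (x) and anterior-posterior (y) axes.

    Accepts a ``nibabel`` spatial image, or an affine together with the
    grid ``shape``.  For each anatomical axis (RAS convention) the grid
    axis with the largest absolute direction cosine is selected and the
    FOV is that axis' voxel count times its spacing.  An oblique
    acquisition with no dominant axis (max |cosine| < ``min_cosine``)
    triggers a warning but still uses the argmax.
    """
    if hasattr(img_or_affine, "affine"):
        affine = np.asarray(img_or_affine.affine, dtype=float)
        shape = img_or_affine.shape[:3]
    else:
        affine = np.asarray(img_or_affine, dtype=float)
        if shape is None:
            raise ValueError("shape is required when passing a bare affine")
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise ValueError("invalid affine")
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("affine implies non-positive voxel spacing")
    cos = np.abs(rot) / spacing  # cos[anatomical axis, grid axis]
    fovs = []
    for anat, name in ((0, "FOVx"), (1, "FOVy")):
        grid_ax = int(np.argmax(cos[anat]))
        if cos[anat, grid_ax] < min_cosine:
            warnings.warn(
                f"{name}: oblique affine with no dominant grid axis "
                f"(max |cosine| = {cos[anat, grid_ax]:.2f}); using argmax",
                UserWarning,
                stacklevel=2,
            )
        fovs.append(float(shape[grid_ax] * spacing[grid_ax]))
    return fovs[0], fovs[1]


def scan_iqm(
    volume: np.ndarray,
    masks: Mapping[str, np.ndarray],
    affine: np.ndarray,
    *,
    cjv_variant: str = "sd",
) -> IQMRecord:
    """All IQMs for a single scan.

    Smoothness is estimated on the residual volume (intensity minus the
    segment mean) within the head (GM plus WM), so that tissue contrast
    does not masquerade as smoothness.
    """
    vol = np.asarray(volume, dtype=float)
    stats = tissue_stats(vol, masks)
    head = np.asarray(masks["gm"], bool) | np.asarray(masks["wm"], bool)
    residual = vol.copy()
    residual[np.asarray(masks["gm"], bool)] -= stats.mu_gm
    residual[np.asarray(masks["wm"], bool)] -= stats.mu_wm
    spacing = tuple(np.linalg.norm(np.asarray(affine, float)[:3, :3], axis=0))
    smooth = fwhm(residual, spacing, head)
    fovx, fovy = fov_from_header(np.asarray(affine, float), vol.shape)
    return IQMRecord(
        cnr=cnr(stats),
        fwhm_mm=smooth.mean_mm,
        fovx_mm=fovx,
        fovy_mm=fovy,
        cjv=cjv(stats, variant=cjv_variant),
        efc=efc(vol),
        fwhm_axes_mm=smooth.axes_mm,
    )


def session_iqm(
    scans: Iterable[IQMRecord] | pd.DataFrame, *, fov_tol: float = 1e-6
) -> IQMRecord:
    """Aggregate per-scan IQMs of one session's back-to-back repeats.

    CNR, FWHM, CJV and EFC are averaged arithmetically across scans; the
    FOV comes from the shared acquisition geometry and must be identical
    across scans (same-sequence assumption) — a mismatch is an error.
    """
    if isinstance(scans, pd.DataFrame):
        df = scans
    else:
        df = pd.DataFrame([s.as_dict() for s in scans])
    if df.empty:
        raise ValueError("session_iqm requires at least one scan")
    for col in ("fovx_mm", "fovy_mm"):
        vals = df[col].to_numpy(float)
        if np.ptp(vals) > fov_tol:
            raise ValueError(
                f"{col} differs between back-to-back scans of one session "
                f"(range {np.ptp(vals):.6g} mm); scans must share one acquisition geometry"
            )
    return IQMRecord(
        cnr=float(df["cnr"].mean()),
        fwhm_mm=float(df["fwhm_mm"].mean()),
        fovx_mm=float(df["fovx_mm"].iloc[0]),
        fovy_mm=float(df["fovy_mm"].iloc[0]),
        cjv=float(df["cjv"].mean()) if "cjv" in df else float("nan"),
        efc=float(df["efc"].mean()) if "efc" in df else float("nan"),
    )
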