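"""Synthetic cohorts and tissue phantoms for acquisition-sequence QC.

This module emulates the structure of a "traveling human phantom" study:
one subject scanned repeatedly across many scanner/sequence combinations,
with 2-6 back-to-back repeat scans per scanning session and hippocampus
volume (HV) estimates produced by a panel of automated volumetry tools for
both hemispheres.  Each scanning session represents one acquisition
sequence.  A configurable fraction of sessions is planted as "poor":
their within-session HV noise is inflated and their session-level image
quality metrics (FOVx, CNR, ...) are drawn from shifted distributions.

Everything downstream of real image data (stability scoring, CART
training, evaluation) can therefore be exercised end to end without any
external dataset.  The generator is not an MR physics simulator: HV noise
is multiplicative Gaussian parameterized by a per-tool coefficient of
variation, and phantom volumes are piecewise-constant tissue balls with
additive Gaussian noise, optional Gaussian smoothing and a smooth
polynomial bias field.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "HEMISPHERES",
    "DEFAULT_SCANS_PER_SESSION_PMF",
    "ToolProfile",
    "CohortConfig",
    "PhantomSpec",
    "default_tool_profiles",
    "default_iqm_distributions",
    "generate_cohort",
    "generate_rule_cohort",
    "generate_phantom",
]

HEMISPHERES = ("left", "right")

#: Distribution of the number of back-to-back repeat scans per session
#: (8/37/67/9/1 sessions with 2/3/4/5/6 scans out of 122; median 4).
DEFAULT_SCANS_PER_SESSION_PMF: dict[int, float] = {
    2: 8 / 122,
    3: 37 / 122,
    4: 67 / 122,
    5: 9 / 122,
    6: 1 / 122,
}


@dataclass(frozen=True)
class ToolProfile:
    """Generating parameters of one automated volumetry tool.

    Parameters
    ----------
    tool_id:
        Short identifier (single letters by default).
    mean_hv_ml:
        True mean hippocampus volume in ml per hemisphere, ``(left, right)``.
        Real tools differ widely (roughly 2-6 ml) because of different
        anatomical hippocampus definitions.
    cov_pct:
        Within-session coefficient of variation of the tool's HV estimates
        on a well-behaved ("good") acquisition sequence, in percent.
    """

    tool_id: str
    mean_hv_ml: tuple[float, float]
    cov_pct: float

    def __post_init__(self) -> None:
        if self.cov_pct < 0:
            raise ValueError(f"cov_pct must be >= 0, got {self.cov_pct}")
        if any(m <= 0 for m in self.mean_hv_ml):
            raise ValueError("mean_hv_ml entries must be positive")


def default_tool_profiles(
    n_tools: int = 19, unstable_tool_factor: float = 8.0
) -> list[ToolProfile]:
    """Deterministic panel of volumetry tools.

    ``n_tools - 1`` stable tools span mean HVs of 2.15-5.99 ml (left; right
    7% smaller) and within-session CoVs of 0.3-1.8%.  The last tool is a
    deliberately unstable one whose CoV is ``unstable_tool_factor`` times
    the median stable CoV, exercising the tool-exclusion rule downstream.
    With ``unstable_tool_factor <= 1`` all tools are stable.
    """
    if n_tools < 1:
        raise ValueError("n_tools must be >= 1")
    letters = [
        a + b for a in [""] + list(string.ascii_uppercase) for b in string.ascii_uppercase
    ]
    unstable = unstable_tool_factor > 1.0 and n_tools >= 2
    n_stable = n_tools - 1 if unstable else n_tools
    left = np.linspace(2.15, 5.99, n_stable)
    covs = np.geomspace(0.3, 1.8, n_stable) if n_stable > 1 else np.array([0.9])
    profiles = [
        ToolProfile(letters[i], (float(left[i]), float(0.93 * left[i])), float(covs[i]))
        for i in range(n_stable)
    ]
    if unstable:
        profiles.append(
            ToolProfile(
                letters[n_stable],
                (3.5, 3.3),
                float(unstable_tool_factor * np.median(covs)),
            )
        )
    return profiles


def default_iqm_distributions() -> dict:
    """Class-conditional session IQM distributions.

    Poor sessions are a mixture: a fraction ``fovx_low_fraction`` has a
    narrow left-right field of view (below 150 mm) with otherwise normal
    contrast, the remainder has adequate FOVx but low contrast-to-noise
    ratio (below ~3.1).  Good sessions have wide FOVx and high CNR.  No
    per-class IQM parameters are reported for the real cohort; these
    defaults are chosen to give a clearly separable two-predictor rule
    (FOVx, then CNR), which is the structure the CART is meant to recover.
    """
    good_fovx = {"kind": "normal", "mean": 225.0, "sd": 30.0, "min": 155.0, "max": 300.0}
    good_cnr = {"kind": "normal", "mean": 4.3, "sd": 0.6, "min": 3.25, "max": 8.0}
    fovy = {"kind": "normal", "mean": 230.0, "sd": 20.0, "min": 170.0, "max": 300.0}
    return {
        "good": {
            "fovx_mm": good_fovx,
            "fovy_mm": fovy,
            "cnr": good_cnr,
            "fwhm_mm": {"kind": "normal", "mean": 3.2, "sd": 0.35, "min": 2.0},
        },
        "poor": {
            "fovx_low_fraction": 0.6,
            "fovx_low": {"kind": "normal", "mean": 140.0, "sd": 4.0, "min": 120.0, "max": 148.0},
            "fovx_ok": good_fovx,
            "cnr_low": {"kind": "normal", "mean": 2.6, "sd": 0.25, "min": 1.5, "max": 3.0},
            "cnr_ok": good_cnr,
            "fovy_mm": fovy,
            # mild shift only: smoothness and FOVy are weak predictors by design
            "fwhm_mm": {"kind": "normal", "mean": 3.35, "sd": 0.4, "min": 2.2},
        },
    }


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic QC cohort.

    Attributes
    ----------
    n_sessions:
        Number of scanning sessions (acquisition sequences); default 122.
    scans_per_session:
        Probability mass function over the number of back-to-back scans,
        support within {2..6}.
    tool_profiles:
        Panel of :class:`ToolProfile`; defaults to 18 stable tools plus one
        unstable tool (see :func:`default_tool_profiles`).
    poor_fraction:
        Probability that a session is planted "poor"; default 27/122.
    poor_noise_multiplier:
        Factor (> 1) applied to every tool's within-session CoV in planted
        poor sessions.
    iqm_distributions:
        Class-conditional session IQM parameters, see
        :func:`default_iqm_distributions`.
    seed:
        Seed for all randomness of the generator.
    """

    n_sessions: int = 122
    scans_per_session: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCANS_PER_SESSION_PMF)
    )
    tool_profiles: Sequence[ToolProfile] | None = None
    unstable_tool_factor: float = 8.0
    n_tools: int = 19
    poor_fraction: float = 27 / 122
    poor_noise_multiplier: float = 3.0
    iqm_distributions: dict | None = None
    seed: int = 0

    def resolved_tool_profiles(self) -> list[ToolProfile]:
        if self.tool_profiles is not None:
            return list(self.tool_profiles)
        return default_tool_profiles(self.n_tools, self.unstable_tool_factor)

    def validate(self) -> None:
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        tools = self.resolved_tool_profiles()
        if len(tools) < 1:
            raise ValueError("at least one volumetry tool is required")
        if not 0.0 <= self.poor_fraction <= 1.0:
            raise ValueError("poor_fraction must lie in [0, 1]")
        if self.poor_noise_multiplier <= 0:
            raise ValueError("poor_noise_multiplier must be > 0")
        pmf = dict(self.scans_per_session)
        if not pmf:
            raise ValueError("scans_per_session must be non-empty")
        if not set(pmf) <= {2, 3, 4, 5, 6}:
            raise ValueError("scans_per_session support must be within {2..6}")
        total = float(sum(pmf.values()))
        if total <= 0 or any(p < 0 for p in pmf.values()):
            raise ValueError("scans_per_session probabilities must be >= 0 and sum > 0")


def _draw(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    kind = dist.get("kind", "normal")
    if kind == "normal":
        x = rng.normal(dist["mean"], dist["sd"], size)
    elif kind == "uniform":
        x = rng.uniform(dist["low"], dist["high"], size)
    else:  # pragma: no cover - config error path
        raise ValueError(f"unknown distribution kind {kind!r}")
    lo = dist.get("min", -np.inf)
    hi = dist.get("max", np.inf)
    return np.clip(x, lo, hi)


def _sample_session_iqm(
    rng: np.random.Generator, labels: np.ndarray, dists: dict
) -> pd.DataFrame:
    n = len(labels)
    out = pd.DataFrame(index=np.arange(n))
    good, poor = dists["good"], dists["poor"]
    is_poor = labels == "poor"
    fovx = _draw(rng, good["fovx_mm"], n)
    fovy = _draw(rng, good["fovy_mm"], n)
    cnr = _draw(rng, good["cnr"], n)
    fwhm = _draw(rng, good["fwhm_mm"], n)
    # poor sessions: mixture of narrow-FOVx (normal CNR) and low-CNR (normal FOVx)
    low_fov = is_poor & (rng.random(n) < poor["fovx_low_fraction"])
    low_cnr = is_poor & ~low_fov
    fovx[low_fov] = _draw(rng, poor["fovx_low"], int(low_fov.sum()))
    fovx[low_cnr] = _draw(rng, poor["fovx_ok"], int(low_cnr.sum()))
    cnr[low_cnr] = _draw(rng, poor["cnr_low"], int(low_cnr.sum()))
    cnr[low_fov] = _draw(rng, poor["cnr_ok"], int(low_fov.sum()))
    fwhm[is_poor] = _draw(rng, poor["fwhm_mm"], int(is_poor.sum()))
    fovy[is_poor] = _draw(rng, poor["fovy_mm"], int(is_poor.sum()))
    out["fovx_mm"] = fovx
    out["fovy_mm"] = fovy
    out["cnr"] = cnr
    out["fwhm_mm"] = fwhm
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one QC cohort.

    Returns
    -------
    scans:
        Long-format table with one row per (session, scan, tool, hemisphere)
        and columns ``session_id, scan_index, tool_id, hemisphere, hv_ml``.
        The HV of scan *s* in session *j* for tool *t* / hemisphere *h* is
        ``mean_hv(t, h) * (1 + eps)`` with
        ``eps ~ Normal(0, cov(t)/100 * m_j)`` and ``m_j`` the poor-session
        noise multiplier (1 for good sessions).
    session_iqm:
        One row per session with columns
        ``session_id, fovx_mm, fovy_mm, cnr, fwhm_mm``.
    labels:
        One row per session with columns ``session_id, planted_label``
        ("good"/"poor").

    Identical configs (including seed) reproduce identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tools = config.resolved_tool_profiles()
    n = config.n_sessions
    session_ids = np.arange(1, n + 1)

    labels = np.where(rng.random(n) < config.poor_fraction, "poor", "good")
    pmf = dict(config.scans_per_session)
    counts = np.array(sorted(pmf))
    probs = np.array([pmf[k] for k in counts], dtype=float)
    probs = probs / probs.sum()
    n_scans = rng.choice(counts, size=n, p=probs)

    rows: list[tuple] = []
    for j, sid in enumerate(session_ids):
        mult = config.poor_noise_multiplier if labels[j] == "poor" else 1.0
        for tool in tools:
            sd = tool.cov_pct / 100.0 * mult
            for h, hemi in enumerate(HEMISPHERES):
                eps = rng.normal(0.0, sd, int(n_scans[j])) if sd > 0 else np.zeros(int(n_scans[j]))
                # guard against non-physical negative volumes at extreme noise
                hv = tool.mean_hv_ml[h] * np.maximum(1.0 + eps, 0.01)
                for s, v in enumerate(hv, start=1):
                    rows.append((int(sid), s, tool.tool_id, hemi, float(v)))
    scans = pd.DataFrame(
        rows, columns=["session_id", "scan_index", "tool_id", "hemisphere", "hv_ml"]
    )

    dists = config.iqm_distributions or default_iqm_distributions()
    iqm = _sample_session_iqm(rng, labels, dists)
    iqm.insert(0, "session_id", session_ids)
    label_df = pd.DataFrame({"session_id": session_ids, "planted_label": labels})
    return scans, iqm, label_df


def generate_rule_cohort(
    n_sessions: int = 200,
    seed: int = 0,
    *,
    fovx_cutoff: float = 150.0,
    cnr_cutoff: float = 3.1,
    fovx_poor_fraction: float = 0.18,
    cnr_poor_fraction: float = 0.12,
    label_flip_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Session IQM table whose labels follow a known two-predictor rule.

    Labels are ``poor`` iff ``FOVx < fovx_cutoff`` or (otherwise)
    ``CNR < cnr_cutoff``; features are drawn from continuous distributions
    straddling the cutoffs, so a depth-2 tree can recover both thresholds
    to within one inter-point gap.  The narrow-FOVx group is drawn with
    *high* CNR so that the field of view carries more class information
    than the contrast and is preferred for the first split.
    ``label_flip_fraction`` optionally flips that fraction of labels at
    random (label noise).
    """
    rng = np.random.default_rng(seed)
    n = int(n_sessions)
    u = rng.random(n)
    low_fov = u < fovx_poor_fraction
    low_cnr = (~low_fov) & (u < fovx_poor_fraction + cnr_poor_fraction)
    fovx = rng.uniform(fovx_cutoff + 2.0, 268.0, n)
    fovx[low_fov] = rng.uniform(128.0, fovx_cutoff - 2.0, int(low_fov.sum()))
    cnr = rng.uniform(cnr_cutoff + 0.05, 5.5, n)
    cnr[low_cnr] = rng.uniform(2.0, cnr_cutoff - 0.05, int(low_cnr.sum()))
    cnr[low_fov] = rng.uniform(3.5, 5.5, int(low_fov.sum()))
    iqm = pd.DataFrame(
        {
            "session_id": np.arange(1, n + 1),
            "fovx_mm": fovx,
            "fovy_mm": rng.normal(230.0, 20.0, n),
            "cnr": cnr,
            "fwhm_mm": rng.normal(3.5, 0.4, n),
        }
    )
    poor = (fovx < fovx_cutoff) | (cnr < cnr_cutoff)
    if label_flip_fraction > 0:
        flip = rng.random(n) < label_flip_fraction
        poor = poor ^ flip
    labels = pd.Series(np.where(poor, "poor", "good"), index=iqm.index, name="label")
    return iqm, labels


@dataclass
class PhantomSpec:
    """Parameters of a geometric three-tissue phantom volume.

    A centered "head" ball (gray matter shell around a white matter core)
    in an air background.  Intensities are tissue means plus independent
    Gaussian noise, optionally Gaussian-smoothed to ``smooth_fwhm_mm`` and
    multiplied by a smooth low-order polynomial bias field whose maximum
    fractional deviation is ``bias_amplitude``.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mean_air: float = 5.0
    mean_gm: float = 60.0
    mean_wm: float = 100.0
    sd_air: float = 5.0
    sd_gm: float = 10.0
    sd_wm: float = 10.0
    smooth_fwhm_mm: float = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape must be 3 axes of at least 16 voxels each")
        if any(d <= 0 for d in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if min(self.sd_air, self.sd_gm, self.sd_wm) < 0:
            raise ValueError("tissue SDs must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, dict[str, np.ndarray], tuple[float, float, float]]:
    """Simulate a phantom volume with ground-truth tissue masks.

    Returns ``(volume, masks, spacing_mm)`` where ``masks`` holds disjoint
    boolean arrays ``gm``, ``wm`` and ``air`` that cover the whole grid.
    A requested smoothing FWHM below the smallest voxel dimension cannot be
    represented on the grid; a warning is emitted and no smoothing applied.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = tuple(float(d) for d in spec.spacing_mm)

    coords = np.meshgrid(
        *[(np.arange(s) - (s - 1) / 2.0) * d for s, d in zip(shape, spacing)],
        indexing="ij",
    )
    r = np.sqrt(sum(c**2 for c in coords))
    extent = min(s * d for s, d in zip(shape, spacing))
    head = r <= 0.42 * extent
    wm = r <= 0.26 * extent
    gm = head & ~wm
    air = ~head
    masks = {"gm": gm, "wm": wm, "air": air}

    mean_map = np.full(shape, spec.mean_air, dtype=float)
    mean_map[gm] = spec.mean_gm
    mean_map[wm] = spec.mean_wm
    sd_map = np.full(shape, spec.sd_air, dtype=float)
    sd_map[gm] = spec.sd_gm
    sd_map[wm] = spec.sd_wm
    volume = mean_map + rng.standard_normal(shape) * sd_map

    if spec.smooth_fwhm_mm > 0:
        if spec.smooth_fwhm_mm < min(spacing):
            warnings.warn(
                "requested smoothing FWHM is below the voxel spacing; skipping smoothing",
                UserWarning,
                stacklevel=2,
            )
        else:
            sigma_vox = [spec.smooth_fwhm_mm * _FWHM_TO_SIGMA / d for d in spacing]
            volume = ndimage.gaussian_filter(volume, sigma_vox)

    if spec.bias_amplitude > 0:
        u, v, w = [c / c.max() for c in coords]  # each in [-1, 1]
        c = rng.uniform(-1.0, 1.0, 9)
        poly = (
            c[0] * u + c[1] * v + c[2] * w
            + c[3] * u * v + c[4] * u * w + c[5] * v * w
            + c[6] * u**2 + c[7] * v**2 + c[8] * w**2
        )
        peak = np.max(np.abs(poly))
        if peak > 0:
            volume = volume * (1.0 + spec.bias_amplitude * poly / peak)

    return volume, masks, spacing
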