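"""Session-level test-retest stability scoring and good/poor labeling.

The stability of an acquisition sequence is measured from the hippocampus
volume (HV) estimates of repeated back-to-back scans in one scanning
session.  For each volumetry tool and hemisphere separately:

1. the within-session coefficient of variation
   ``CoV = 100 * SD / mean`` is computed across the session's repeat scans;
2. sessions outside the Tukey fences (1.5 x IQR beyond the quartiles of
   the CoV across sessions) are flagged as outliers;
3. a Box-Cox transformation, fitted by maximum likelihood on the
   non-outlier sessions, is applied to all sessions to reduce the
   right-skew of CoV values;
4. the transformed values are standardized to z-scores using the
   non-outlier mean and SD (outliers still receive z-scores; they are
   only excluded from estimating the reference moments).

The z-scores are then averaged across all retained tools and both
hemispheres per session, tools with grossly elevated within-session
variability having been dropped first.  A zero-mean Gaussian is fitted to
the histogram of the per-session mean z-scores; its SD sets the cutoff:
a session is labeled "poor" iff its mean z-score exceeds
``cutoff_multiplier * SD`` (default +1 SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "TransformModel",
    "LabelingModel",
    "within_session_cov",
    "tukey_outliers",
    "fit_transform",
    "exclude_unstable_tools",
    "mean_session_z",
    "fit_gaussian_sd",
    "label_sessions",
    "compute_stability_table",
    "StabilitySessionLabeler",
]

GOOD, POOR = "good", "poor"


@dataclass(frozen=True)
class TransformModel:
    """Fitted Box-Cox + standardization parameters for one (tool, hemisphere)."""

    lmbda: float
    shift: float
    ref_mean: float
    ref_sd: float

    def __post_init__(self) -> None:
        if self.ref_sd <= 0:
            raise ValueError("ref_sd must be > 0")

    def apply(self, covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (Box-Cox values, z-scores) for raw CoVs."""
        bc = special.boxcox(np.asarray(covs, float) + self.shift, self.lmbda)
        return bc, (bc - self.ref_mean) / self.ref_sd


@dataclass(frozen=True)
class LabelingModel:
    """Gaussian-cutoff labeling parameters."""

    gaussian_sd: float
    cutoff_multiplier: float = 1.0
    excluded_tools: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be > 0")

    @property
    def cutoff(self) -> float:
        return self.cutoff_multiplier * self.gaussian_sd


def within_session_cov(volumes: Sequence[float]) -> float:
    """Within-session coefficient of variation, in percent.

    ``100 * SD / mean`` across the back-to-back repeat scans, with the
    sample SD (denominator n-1): sessions have only 2-6 repeats, so the
    small-sample convention matters and is pinned.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("within-session CoV requires at least 2 repeat scans")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("within-session CoV requires a positive mean volume")
    return 100.0 * float(v.std(ddof=1)) / mean


def tukey_outliers(covs: Sequence[float], *, k: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier flags for per-session CoVs of one tool/hemisphere.

    A session is an outlier if its CoV lies above ``Q3 + k*IQR`` or below
    ``Q1 - k*IQR``, with linearly interpolated quartiles over the full set.
    """
    x = np.asarray(covs, dtype=float)
    if x.size < 4:
        raise ValueError("Tukey fences require at least 4 sessions")
    q1, q3 = np.percentile(x, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    return (x > q3 + k * iqr) | (x < q1 - k * iqr)


def fit_transform(
    covs: Sequence[float],
    outliers: Sequence[bool] | None = None,
    *,
    lmbda: float | None = None,
    zero_shift: float = 1e-6,
) -> tuple[TransformModel, np.ndarray, np.ndarray]:
    """Box-Cox transform and z-score CoVs against the non-outlier sessions.

    The Box-Cox exponent is fitted by maximum likelihood on the
    non-outlier CoVs (or forced via ``lmbda``); *all* sessions, including
    outliers, are then transformed with that exponent and standardized by
    the mean and sample SD of the transformed non-outlier values, so that
    non-outlier z-scores have mean 0 and SD 1 exactly.  CoVs of exactly
    zero are handled by a fixed shift ``zero_shift`` applied to every
    value (Box-Cox needs strictly positive input); the shift is recorded
    in the returned model.

    Returns ``(model, boxcox_values, z_scores)``.
    """
    x = np.asarray(covs, dtype=float)
    out = np.zeros(x.size, dtype=bool) if outliers is None else np.asarray(outliers, bool)
    if out.shape != x.shape:
        raise ValueError("outlier flags must match covs in length")
    if np.any(x < 0):
        raise ValueError("CoV values must be >= 0")
    if (~out).sum() < 4:
        raise ValueError("need at least 4 non-outlier sessions to fit the transform")
    shift = zero_shift if np.any(x == 0) else 0.0
    shifted = x + shift
    ref = shifted[~out]
    if lmbda is None:
        _, lmbda = stats.boxcox(ref)
    lmbda = float(lmbda)
    bc = special.boxcox(shifted, lmbda)
    ref_bc = bc[~out]
    ref_sd = float(ref_bc.std(ddof=1))
    if ref_sd == 0:
        raise ValueError("non-outlier CoVs have zero variance; z-scores undefined")
    model = TransformModel(lmbda, shift, float(ref_bc.mean()), ref_sd)
    return model, bc, (bc - model.ref_mean) / model.ref_sd


def exclude_unstable_tools(
    tool_mean_cov: Mapping[str, float] | pd.Series, *, factor: float = 3.0
) -> list[str]:
    """Drop tools with grossly elevated within-session variability.

    A tool is excluded when its mean non-outlier CoV exceeds ``factor``
    times the median across tools (default 3; real unstable tools have
    shown several-fold elevated variability).  Returns the kept tool ids
    in input order; ``factor = inf`` disables the rule.
    """
    s = pd.Series(tool_mean_cov, dtype=float)
    if len(s) < 2:
        raise ValueError("tool exclusion requires at least 2 tools")
    med = float(s.median())
    kept = [t for t, v in s.items() if not v > factor * med]
    if not kept:
        raise ValueError("tool-exclusion rule dropped every tool")
    return kept


def mean_session_z(
    stability: pd.DataFrame, kept_tools: Sequence[str]
) -> pd.Series:
    """Per-session mean z-score over the kept tools and both hemispheres.

    ``stability`` is the long table produced by
    :func:`compute_stability_table` (columns ``tool_id, hemisphere,
    session_id, z``).  The average is unweighted over the kept
    (tool, hemisphere) cells; a session missing any kept cell is an error
    (sessions with incomplete tool coverage must be excluded upstream).
    """
    kept = set(kept_tools)
    sub = stability[stability["tool_id"].isin(kept)]
    wide = sub.pivot_table(
        index="session_id", columns=["tool_id", "hemisphere"], values="z", aggfunc="first"
    )
    expected = len(kept) * 2  # both hemispheres, always
    if wide.shape[1] != expected or wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist() if wide.shape[1] else "all"
        raise ValueError(
            f"missing z-scores for some (tool, hemisphere) cells: {missing}; "
            "every kept tool/hemisphere needs a value for every session"
        )
    return wide.mean(axis=1).rename("mean_z")


def fit_gaussian_sd(
    mean_z: Sequence[float],
    *,
    bin_width: float = 0.1,
    hist_range_sd: float = 4.0,
) -> float:
    """SD of a zero-mean Gaussian fitted to the histogram of mean z-scores.

    The histogram (default bin width 0.1, spanning +/- ``hist_range_sd``
    sample SDs) is fitted by least squares with the amplitude and SD free
    and the mean fixed at zero.  Fitting a curve to the histogram rather
    than taking the raw sample SD makes the scale estimate robust to a
    heavy upper tail of genuinely unstable sessions.
    """
    z = np.asarray(mean_z, dtype=float)
    if z.size < 20:
        raise ValueError("Gaussian fit requires at least 20 sessions")
    spread = float(z.std(ddof=1))
    if spread == 0:
        raise ValueError("degenerate mean z-score distribution (zero spread)")
    half = hist_range_sd * spread
    edges = np.arange(-half, half + bin_width, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if int((counts > 0).sum()) <= 2:
        raise ValueError("degenerate histogram: fewer than 3 occupied bins")

    def _gauss(x: np.ndarray, amp: float, sd: float) -> np.ndarray:
        return amp * np.exp(-(x**2) / (2.0 * sd**2))

    p0 = (float(counts.max()), spread)
    popt, _ = optimize.curve_fit(
        _gauss, centers, counts, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000
    )
    return float(abs(popt[1]))


def label_sessions(
    mean_z: pd.Series | Sequence[float], model: LabelingModel
) -> pd.Series:
    """Label sessions good/poor by the Gaussian-SD cutoff.

    A session is "poor" iff its mean z-score is strictly larger than
    ``cutoff_multiplier * gaussian_sd``; a score exactly at the cutoff is
    "good".
    """
    z = pd.Series(mean_z, dtype=float)
    return pd.Series(
        np.where(z > model.cutoff, POOR, GOOD), index=z.index, name="label"
    )


def compute_stability_table(
    scans: pd.DataFrame,
    *,
    lmbda: float | None = None,
    zero_shift: float = 1e-6,
    tukey_k: float = 1.5,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TransformModel]]:
    """Per-(tool, hemisphere, session) CoV, outlier flag, Box-Cox value and z.

    ``scans`` is the long scan table (columns ``session_id, scan_index,
    tool_id, hemisphere, hv_ml``).  Returns the long stability table and
    the fitted transform per (tool, hemisphere).
    """
    required = {"session_id", "tool_id", "hemisphere", "hv_ml"}
    if not required <= set(scans.columns):
        raise ValueError(f"scan table must have columns {sorted(required)}")
    covs = (
        scans.groupby(["tool_id", "hemisphere", "session_id"], sort=True)["hv_ml"]
        .apply(lambda v: within_session_cov(v.to_numpy()))
        .rename("cov_pct")
        .reset_index()
    )
    frames = []
    transforms: dict[tuple[str, str], TransformModel] = {}
    for (tool, hemi), grp in covs.groupby(["tool_id", "hemisphere"], sort=True):
        x = grp["cov_pct"].to_numpy()
        out = tukey_outliers(x, k=tukey_k)
        model, bc, z = fit_transform(x, out, lmbda=lmbda, zero_shift=zero_shift)
        transforms[(tool, hemi)] = model
        g = grp.copy()
        g["is_outlier"] = out
        g["bc_value"] = bc
        g["z"] = z
        frames.append(g)
    table = pd.concat(frames, ignore_index=True)
    return table, transforms


class StabilitySessionLabeler(BaseEstimator):
    """Label scanning sessions good/poor from repeat-scan HV estimates.

    Runs the full stability pipeline on a long scan table: within-session
    CoV per (tool, hemisphere), Tukey outlier flagging, Box-Cox + z-score
    standardization against non-outlier sessions, exclusion of grossly
    unstable tools, tool/hemisphere averaging, zero-mean Gaussian fit to
    the mean z-score histogram, and the +1 SD cutoff.

    Parameters
    ----------
    tool_exclusion_factor:
        Drop a tool when its mean non-outlier CoV exceeds this multiple of
        the median across tools.  ``inf`` disables the rule.
    cutoff_multiplier:
        Sessions with mean z above ``cutoff_multiplier * gaussian_sd_``
        are labeled poor.
    boxcox_lmbda:
        Force the Box-Cox exponent instead of fitting it by ML.
    bin_width, hist_range_sd:
        Histogram parameters of the Gaussian-SD fit.

    Attributes (after :meth:`fit`)
    ------------------------------
    stability_ : long per-(tool, hemisphere, session) table.
    transforms_ : fitted :class:`TransformModel` per (tool, hemisphere).
    kept_tools_, excluded_tools_ : tool ids retained / dropped.
    session_scores_ : DataFrame with ``mean_z``, ``label``, ``n_tools_used``.
    gaussian_sd_ : fitted Gaussian SD (the labeling scale).
    labeling_model_ : :class:`LabelingModel`.
    labels_ : per-session good/poor labels (Series indexed by session id).
    """

    def __init__(
        self,
        tool_exclusion_factor: float = 3.0,
        cutoff_multiplier: float = 1.0,
        boxcox_lmbda: float | None = None,
        zero_shift: float = 1e-6,
        tukey_k: float = 1.5,
        bin_width: float = 0.1,
        hist_range_sd: float = 4.0,
    ) -> None:
        self.tool_exclusion_factor = tool_exclusion_factor
        self.cutoff_multiplier = cutoff_multiplier
        self.boxcox_lmbda = boxcox_lmbda
        self.zero_shift = zero_shift
        self.tukey_k = tukey_k
        self.bin_width = bin_width
        self.hist_range_sd = hist_range_sd

    def fit(self, scans: pd.DataFrame, y: None = None) -> "StabilitySessionLabeler":
        table, transforms = compute_stability_table(
            scans,
            lmbda=self.boxcox_lmbda,
            zero_shift=self.zero_shift,
            tukey_k=self.tukey_k,
        )
        tool_mean = (
            table[~table["is_outlier"]].groupby("tool_id")["cov_pct"].mean()
        )
        kept = exclude_unstable_tools(tool_mean, factor=self.tool_exclusion_factor)
        mean_z = mean_session_z(table, kept)
        sd = fit_gaussian_sd(
            mean_z.to_numpy(), bin_width=self.bin_width, hist_range_sd=self.hist_range_sd
        )
        model = LabelingModel(
            gaussian_sd=sd,
            cutoff_multiplier=self.cutoff_multiplier,
            excluded_tools=tuple(t for t in tool_mean.index if t not in kept),
        )
        labels = label_sessions(mean_z, model)

        self.stability_ = table
        self.transforms_ = transforms
        self.kept_tools_ = list(kept)
        self.excluded_tools_ = list(model.excluded_tools)
        self.gaussian_sd_ = sd
        self.labeling_model_ = model
        self.session_scores_ = pd.DataFrame(
            {
                "mean_z": mean_z,
                "label": labels,
                "n_tools_used": len(kept),
            }
        )
        self.labels_ = labels
        return self

    def fit_predict(self, scans: pd.DataFrame, y: None = None) -> pd.Series:
        return self.fit(scans).labels_
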