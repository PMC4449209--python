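"""Registration-error evaluation: reference reconstruction, TRE/FRE,
LOOCV, non-parametric statistics, and the MSE translation-landscape sweep.

Two spatial contexts are measured.  The *pairwise* error is the
post-registration Euclidean distance between homologous landmark pairs on
adjacent sections: it characterises each pairwise registration
independently and captures topology errors.  The *accumulated* error maps a
landmark into the section-1 frame through both the algorithm's and the
reference transform chains and measures the discrepancy: it captures
spatial bias propagating through the composed stack (geometry errors) that
pairwise error alone cannot see.

Both error kinds come in two flavours: FRE (distance over the landmark
pairs that defined the fit — best case) and TRE (distance over withheld
pairs — realistic).  Descriptive statistics follow the non-parametric
conventions used for skewed error distributions: median ± IQR, rank-based
95% confidence intervals on the median, per-section maxima summarised as
mean ± SD, and a non-parametric prediction interval whose level is
P = (N − 1)/(N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .geometry import AffineTransform2D, TransformChain, compose
from .image import SectionImage, mse, to_grayscale
from .intensity import _MSEObjective  # overlap-MSE machinery shared with registration

__all__ = [
    "ReferenceLandmarkSet",
    "ErrorReport",
    "ComparisonReport",
    "build_reference_reconstruction",
    "pairwise_error",
    "accumulated_error",
    "loocv_tre",
    "fre",
    "summarize",
    "median_rank_ci",
    "compare_methods",
    "mse_landscape_sweep",
    "prediction_interval_upper",
    "read_landmark_pairs_csv",
    "write_landmark_pairs_csv",
]


@dataclass
class ReferenceLandmarkSet:
    """Verified homologous centroid pairs per adjacent section pair.

    ``pairs[k] = (P_I, P_J)``: (n, 2) μm arrays of matched positions on
    section k and section k+1.  Reference landmarks must be disjoint from
    the landmarks that drive the registration — they are the withheld
    targets the TRE is measured on.
    """

    pairs: dict
    verified: bool = True

    def sections(self) -> list:
        return sorted(self.pairs)

    def n_pairs(self) -> int:
        return int(sum(len(p[0]) for p in self.pairs.values()))


@dataclass
class ErrorReport:
    """Per-landmark registration errors with non-parametric summaries."""

    errors: np.ndarray
    by_section: dict = field(default_factory=dict)
    kind: str = "TRE"
    context: str = "pairwise"
    median: float = 0.0
    iqr: float = 0.0
    ci95: tuple = (0.0, 0.0)
    section_max: dict = field(default_factory=dict)
    max_mean: float = float("nan")
    max_sd: float = float("nan")

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for sec, errs in sorted(self.by_section.items()):
            for e in errs:
                rows.append({"section": sec, "error_um": e, "kind": self.kind, "context": self.context})
        if not rows:
            rows = [{"section": None, "error_um": e, "kind": self.kind, "context": self.context} for e in self.errors]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return (
            f"{self.context} {self.kind}: median {self.median:.2f} ± {self.iqr:.2f} μm "
            f"(95% CI [{self.ci95[0]:.2f}, {self.ci95[1]:.2f}]), "
            f"per-section max {self.max_mean:.2f} ± {self.max_sd:.2f} μm, n={len(self.errors)}"
        )


# ----------------------------------------------------------------------
# reference reconstruction and error computation
# ----------------------------------------------------------------------

def build_reference_reconstruction(
    refs: ReferenceLandmarkSet, model: str = "affine"
) -> TransformChain:
    """Fit the surrogate ideal chain from verified landmark pairs.

    Each pair list is fit independently (rigid or affine least squares) and
    the fits are composed into a chain anchored at section 1.
    """
    fitter = geometry.fit_rigid if model == "rigid" else geometry.fit_affine
    sections = refs.sections()
    if sections != list(range(1, len(sections) + 1)):
        raise ValueError("reference pairs must cover contiguous section pairs from 1")
    pairwise = []
    for k in sections:
        p_i, p_j = refs.pairs[k]
        try:
            pairwise.append(fitter(p_j, p_i))
        except geometry.DegenerateFitError as exc:
            raise geometry.DegenerateFitError(f"section pair ({k}, {k + 1}): {exc}") from exc
    return TransformChain(pairwise)


def pairwise_error(transform: AffineTransform2D, p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """Post-registration distance ``||p_I − T(p_J)||`` per homologous pair.

    This is the TRE when the pairs are withheld reference landmarks and the
    FRE when they are the landmarks the transform was fitted on; the ideal
    value of both is zero.
    """
    p_i = np.atleast_2d(np.asarray(p_i, dtype=float))
    p_j = np.atleast_2d(np.asarray(p_j, dtype=float))
    return np.linalg.norm(p_i - transform.apply(p_j), axis=1)


def accumulated_error(
    algo_chain: TransformChain, ref_chain: TransformChain, refs: ReferenceLandmarkSet
) -> ErrorReport:
    """Discrepancy of each reference landmark's section-1-frame position
    under the algorithm chain vs the reference chain.

    Landmarks on section k (both sides of the adjacent pairs touching k) are
    mapped through both cumulative transforms; section 1 errors are zero by
    construction.
    """
    if algo_chain.n_sections != ref_chain.n_sections:
        raise ValueError("chains cover different numbers of sections")
    n = algo_chain.n_sections
    per_section_points: dict = {k: [] for k in range(1, n + 1)}
    for k, (p_i, p_j) in refs.pairs.items():
        if not 1 <= k < n + 1:
            raise ValueError(f"reference pair key {k} outside chain sections")
        per_section_points[k].extend(np.atleast_2d(p_i))
        per_section_points[k + 1].extend(np.atleast_2d(p_j))
    by_section = {}
    for k in range(1, n + 1):
        pts = np.array(per_section_points[k]).reshape(-1, 2)
        if len(pts) == 0:
            continue
        a = algo_chain.map_to_reference(k, pts)
        r = ref_chain.map_to_reference(k, pts)
        by_section[k] = np.linalg.norm(a - r, axis=1)
    return summarize(
        np.concatenate([by_section[k] for k in sorted(by_section)]),
        by_section=by_section,
        kind="TRE",
        context="accumulated",
    )


def fre(p_i: np.ndarray, p_j: np.ndarray, model: str = "affine") -> np.ndarray:
    """Fiducial registration error: fit on all pairs, measure on the same."""
    fitter = geometry.fit_rigid if model == "rigid" else geometry.fit_affine
    t = fitter(p_j, p_i)
    return pairwise_error(t, p_i, p_j)


def loocv_tre(p_i: np.ndarray, p_j: np.ndarray, model: str = "affine") -> np.ndarray:
    """Leave-one-out TRE: for each pair, fit on the others and measure the
    withheld pair's error.  Returns n values; a degenerate leave-one-out
    fold is reported as NaN (missing), never fabricated.
    """
    p_i = np.atleast_2d(np.asarray(p_i, dtype=float))
    p_j = np.atleast_2d(np.asarray(p_j, dtype=float))
    n = len(p_i)
    minimum = 2 if model == "rigid" else 3
    if n < minimum + 1:
        raise ValueError(f"LOOCV needs at least {minimum + 1} pairs for the {model} model")
    fitter = geometry.fit_rigid if model == "rigid" else geometry.fit_affine
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            t = fitter(p_j[keep], p_i[keep])
        except geometry.DegenerateFitError:
            out[i] = np.nan
            continue
        out[i] = pairwise_error(t, p_i[i], p_j[i])[0]
    return out


# ----------------------------------------------------------------------
# non-parametric summaries
# ----------------------------------------------------------------------

def median_rank_ci(values: Sequence[float]) -> tuple:
    """Rank-based 95% CI on the median: the sorted values at ranks
    n/2 − 1.96·√n/2 and n/2 + 1.96·√n/2, rounded to the nearest integer rank
    and clamped to [1, n]."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    half_width = 1.96 * np.sqrt(n) / 2.0
    lo = int(np.clip(round(n / 2.0 - half_width), 1, n))
    hi = int(np.clip(round(n / 2.0 + half_width), 1, n))
    return (float(v[lo - 1]), float(v[hi - 1]))


def summarize(
    errors: Sequence[float],
    sections: Sequence[int] | None = None,
    by_section: dict | None = None,
    kind: str = "TRE",
    context: str = "pairwise",
) -> ErrorReport:
    """Median, IQR, rank-based 95% CI, and per-section maxima (mean ± SD)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot summarize an empty error sample")
    if by_section is None:
        if sections is not None:
            sections = np.asarray(sections)
            by_section = {int(s): errors[sections == s] for s in np.unique(sections)}
        else:
            by_section = {}
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    section_max = {k: float(np.max(v)) for k, v in by_section.items() if len(v)}
    maxima = np.array(list(section_max.values())) if section_max else np.array([errors.max()])
    return ErrorReport(
        errors=errors,
        by_section=by_section,
        kind=kind,
        context=context,
        median=float(med),
        iqr=float(q3 - q1),
        ci95=median_rank_ci(errors),
        section_max=section_max,
        max_mean=float(maxima.mean()),
        max_sd=float(maxima.std(ddof=1)) if len(maxima) > 1 else 0.0,
    )


@dataclass
class ComparisonReport:
    """Paired non-parametric comparison of two error samples.

    The Kolmogorov–Smirnov normality screen is reported but not used to
    switch tests: the Wilcoxon signed-rank comparison of medians is always
    the inferential test (registration errors are reliably non-normal).
    """

    ks_stat_a: float
    ks_p_a: float
    ks_stat_b: float
    ks_p_b: float
    wilcoxon_stat: float
    wilcoxon_p: float
    median_a: float
    median_b: float
    n: int

    @property
    def direction(self) -> str:
        if self.median_a == self.median_b:
            return "equal medians"
        return "b > a" if self.median_b > self.median_a else "a > b"


def _ks_normality(x: np.ndarray) -> tuple:
    sd = x.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0)
    stat, p = stats.kstest((x - x.mean()) / sd, "norm")
    return (float(stat), float(p))


def compare_methods(errors_a: Sequence[float], errors_b: Sequence[float]) -> ComparisonReport:
    """Paired Wilcoxon signed-rank test of equal medians (zero differences
    discarded, the standard signed-rank convention), with a KS normality
    screen on each sample."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ks_a, ks_b = _ks_normality(a), _ks_normality(b)
    d = b - a
    if np.all(d == 0):
        w_stat, w_p = float("nan"), 1.0
    else:
        w_stat, w_p = stats.wilcoxon(a, b, zero_method="wilcox")
        w_stat, w_p = float(w_stat), float(w_p)
    return ComparisonReport(
        ks_stat_a=ks_a[0], ks_p_a=ks_a[1], ks_stat_b=ks_b[0], ks_p_b=ks_b[1],
        wilcoxon_stat=w_stat, wilcoxon_p=w_p,
        median_a=float(np.median(a)), median_b=float(np.median(b)), n=len(a),
    )


def prediction_interval_upper(values: Sequence[float]) -> tuple:
    """Non-parametric prediction interval: the sample maximum bounds the
    P% interval with P = (N − 1)/(N + 1).  Returns (upper bound, P in %)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values for a prediction interval")
    return (float(v.max()), 100.0 * (n - 1) / (n + 1))


# ----------------------------------------------------------------------
# MSE translation landscape
# ----------------------------------------------------------------------

def mse_landscape_sweep(
    fixed: SectionImage,
    moving: SectionImage,
    center: AffineTransform2D,
    axis: str = "x",
    range_um: float = 20.0,
    step_um: float = 0.5,
) -> tuple:
    """Sweep the overlap MSE over pure translations about a registration
    optimum.

    Evaluates the grayscale MSE at ``center`` composed with translations
    −range…+range μm along one axis (81 samples at the default ±20 μm /
    0.5 μm) and returns ``(displacements, mse_values, optimum_offset)``
    where the optimum offset is the displacement of the MSE minimum from
    the provided centre — 0 μm means the MSE optimum coincides with the
    landmark-registration optimum.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    n = int(round(2 * range_um / step_um)) + 1
    disps = -range_um + step_um * np.arange(n)
    fixed_g = to_grayscale(fixed)
    moving_g = to_grayscale(moving)
    obj = _MSEObjective(fixed_g, moving_g, fixed.spacing, lambda p: None)
    values = np.empty(n)
    for i, d in enumerate(disps):
        shift = (d, 0.0) if axis == "x" else (0.0, d)
        t = compose(AffineTransform2D.from_translation(*shift), center)
        obj.to_transform = lambda _p, _t=t: _t
        values[i] = obj(None)
    return disps, values, float(disps[int(np.argmin(values))])


# ----------------------------------------------------------------------
# landmark-pair CSV dialect
# ----------------------------------------------------------------------

def write_landmark_pairs_csv(refs: ReferenceLandmarkSet, path) -> None:
    rows = []
    for k, (p_i, p_j) in sorted(refs.pairs.items()):
        for a, b in zip(np.atleast_2d(p_i), np.atleast_2d(p_j)):
            rows.append(
                {
                    "section_index": k,
                    "x_fixed_um": a[0],
                    "y_fixed_um": a[1],
                    "x_moving_um": b[0],
                    "y_moving_um": b[1],
                    "verified": refs.verified,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmark_pairs_csv(path) -> ReferenceLandmarkSet:
    df = pd.read_csv(path)
    pairs = {}
    for k, grp in df.groupby("section_index"):
        pairs[int(k)] = (
            grp[["x_fixed_um", "y_fixed_um"]].to_numpy(dtype=float),
            grp[["x_moving_um", "y_moving_um"]].to_numpy(dtype=float),
        )
    verified = bool(df["verified"].all()) if "verified" in df else True
    return ReferenceLandmarkSet(pairs, verified=verified)


def plot_section_boxplots(report: ErrorReport, ax=None):
    """Box plots of the per-section error distributions (sections on x)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    keys = sorted(report.by_section)
    ax.boxplot([report.by_section[k] for k in keys], tick_labels=[str(k) for k in keys])
    ax.set_xlabel("section")
    ax.set_ylabel(f"{report.context} {report.kind} (μm)")
    return ax
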