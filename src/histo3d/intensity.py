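"""MSE-driven rigid and affine registration by regular-step gradient descent.

The intensity branch mirrors the classical two-level cascade: a coarse rigid
registration on heavily downsampled grayscale images (extents capped at
172 x 264 pixels) initialises everything downstream, and an optional
high-resolution refinement re-optimises rigid then affine parameters on
4 μm/px grayscale images with much smaller step lengths.

The optimizer is a regular-step gradient descent: parameters move along the
scaled negative gradient with the current step length; when the scaled
gradient direction reverses (negative dot product with the previous
direction) the step is multiplied by a relaxation factor, and optimisation
stops once the step falls below the minimum step length.  Gradients are
central finite differences in scaled parameter space.  The walk itself may
transiently increase the metric (which lets it traverse small bumps in the
similarity landscape); the best state visited is tracked, returned, and
recorded in the accepted-state trace, whose MSE sequence is therefore
monotone non-increasing.  Rigid parameters are
(rotation angle about the fixed-image centre, tx, ty); affine parameters are
the four matrix entries (centre-relative) plus the translation.  Scales
down-weight rotation/matrix sensitivity (1e2) relative to translation (1e-2)
so that parameter sensitivities are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import AffineTransform2D
from .image import SectionImage, downsample, downsampled_shape, to_grayscale

__all__ = [
    "OptimizerSettings",
    "RegistrationResult",
    "RegistrationError",
    "low_res_rigid_settings",
    "high_res_rigid_settings",
    "high_res_affine_settings",
    "register_rigid_mse",
    "register_affine_mse",
    "coarse_initialize",
]


class RegistrationError(RuntimeError):
    """The similarity metric became non-finite during optimisation."""


@dataclass(frozen=True)
class OptimizerSettings:
    """Regular-step gradient-descent settings.

    ``parameter_scales`` divide the raw gradient (larger scale = less mobile
    parameter).  ``max_step`` is the initial step length and ``min_step`` the
    convergence criterion, both in scaled parameter space.
    """

    parameter_scales: tuple
    max_step: float
    min_step: float
    max_iterations: int = 200
    relaxation: float = 0.5
    fd_step: float = 0.01  # finite-difference half-step in scaled space

    def __post_init__(self) -> None:
        if not self.min_step < self.max_step:
            raise ValueError("min_step must be smaller than max_step")
        if any(s <= 0 for s in self.parameter_scales):
            raise ValueError("all parameter scales must be positive")
        if not 0 < self.relaxation < 1:
            raise ValueError("relaxation must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


def low_res_rigid_settings() -> OptimizerSettings:
    """Coarse initialisation settings: scales 1e2 (rotation) / 1e-2
    (translation), step lengths 4 down to 0.1."""
    return OptimizerSettings((1e2, 1e-2, 1e-2), max_step=4.0, min_step=0.1)


def high_res_rigid_settings() -> OptimizerSettings:
    """High-resolution refinement: step lengths adjusted to 0.01 / 0.001."""
    return OptimizerSettings((1e2, 1e-2, 1e-2), max_step=0.01, min_step=0.001)


def high_res_affine_settings() -> OptimizerSettings:
    """Affine refinement; matrix entries scaled like rotation (1e2),
    translations 1e-2, mirroring the rigid convention."""
    return OptimizerSettings((1e2,) * 4 + (1e-2,) * 2, max_step=0.01, min_step=0.001)


@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    final_mse: float
    n_iterations: int
    converged: bool
    trace: list = field(default_factory=list, repr=False)

    def trace_mse(self) -> np.ndarray:
        """MSE values of the accepted optimizer states, in order."""
        return np.array([rec["mse"] for rec in self.trace])

    def trace_to_csv(self, path) -> None:
        """Write the accepted-state trace (iteration, step, MSE, parameters)
        as CSV."""
        import pandas as pd

        rows = []
        for rec in self.trace:
            row = {"iteration": rec["iteration"], "step": rec["step"], "mse": rec["mse"]}
            row.update({f"p{i}": v for i, v in enumerate(rec["params"])})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------------
# parameterisations (centre-relative, translations in μm)
# ----------------------------------------------------------------------

def _rigid_from_params(p: np.ndarray, center: np.ndarray) -> AffineTransform2D:
    theta, tx, ty = p
    return AffineTransform2D.from_rotation(theta, center=center, translation=(tx, ty))


def _rigid_to_params(t: AffineTransform2D, center: np.ndarray) -> np.ndarray:
    theta = float(np.arctan2(t.matrix[1, 0], t.matrix[0, 0]))
    resid = t.translation - (center - t.matrix @ center)
    return np.array([theta, resid[0], resid[1]])


def _affine_from_params(p: np.ndarray, center: np.ndarray) -> AffineTransform2D:
    m = np.array([[p[0], p[1]], [p[2], p[3]]])
    t = np.array([p[4], p[5]]) + center - m @ center
    return AffineTransform2D(m, t)


def _affine_to_params(t: AffineTransform2D, center: np.ndarray) -> np.ndarray:
    resid = t.translation - (center - t.matrix @ center)
    m = t.matrix
    return np.array([m[0, 0], m[0, 1], m[1, 0], m[1, 1], resid[0], resid[1]])


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

class _MSEObjective:
    """Overlap-normalised MSE between a fixed raster and a moving raster
    warped through a parameterised transform.

    The metric is computed over the fixed-image domain; moving-image samples
    that fall outside the moving raster are excluded from the mean.
    """

    def __init__(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        spacing: float,
        to_transform: Callable[[np.ndarray], AffineTransform2D],
    ):
        self.fixed = np.asarray(fixed, dtype=float)
        self.moving = np.asarray(moving, dtype=float)
        self.spacing = float(spacing)
        self.to_transform = to_transform
        h, w = self.fixed.shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        self._phys = np.column_stack(
            [cols.ravel() * self.spacing, rows.ravel() * self.spacing]
        )
        self._fixed_flat = self.fixed.ravel()
        self._mh, self._mw = self.moving.shape

    def __call__(self, params: np.ndarray) -> float:
        t = self.to_transform(params)
        try:
            inv = t.invert()
        except Exception:
            return np.inf
        src = inv.apply(self._phys)
        c = src[:, 0] / self.spacing
        r = src[:, 1] / self.spacing
        valid = (c >= 0) & (c <= self._mw - 1) & (r >= 0) & (r <= self._mh - 1)
        if not valid.any():
            return np.inf
        vals = ndimage.map_coordinates(
            self.moving, np.vstack([r[valid], c[valid]]), order=1, mode="nearest"
        )
        d = vals - self._fixed_flat[valid]
        return float(np.mean(d * d))


# ----------------------------------------------------------------------
# regular-step gradient descent
# ----------------------------------------------------------------------

def _regular_step_minimize(objective, p0: np.ndarray, settings: OptimizerSettings):
    """Regular-step gradient descent with best-state tracking.

    The walk itself is blind (a step may transiently increase the metric,
    which lets it traverse small landscape bumps); the step length is
    relaxed whenever the scaled gradient direction reverses.  The returned
    state is the best one visited, and the trace records exactly the
    sequence of improving ("accepted") states, so traced MSE is monotone
    non-increasing.
    """
    scales = np.asarray(settings.parameter_scales, dtype=float)
    p = np.asarray(p0, dtype=float).copy()
    f = objective(p)
    if not np.isfinite(f):
        raise RegistrationError(f"non-finite metric at initial parameters {p.tolist()}")
    p_best, f_best = p.copy(), f
    trace = [{"iteration": 0, "step": settings.max_step, "mse": f, "params": p.copy()}]
    step = settings.max_step
    prev_tg = None
    converged = False
    it = 0
    while it < settings.max_iterations:
        it += 1
        # central finite differences in scaled parameter space
        g = np.zeros_like(p)
        for i in range(len(p)):
            eps = settings.fd_step / scales[i]
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            fp, fm = objective(pp), objective(pm)
            if not (np.isfinite(fp) and np.isfinite(fm)):
                raise RegistrationError(
                    f"non-finite metric at iteration {it}, parameters {p.tolist()}"
                )
            g[i] = (fp - fm) / (2 * eps)
        tg = g / scales
        norm = float(np.linalg.norm(tg))
        if norm == 0.0:
            converged = True
            break
        if prev_tg is not None and float(np.dot(tg, prev_tg)) < 0.0:
            step *= settings.relaxation
        if step < settings.min_step:
            converged = True
            break
        p = p - step * tg / norm
        f = objective(p)
        prev_tg = tg
        if not np.isfinite(f):
            # walked out of the comparable domain: retreat to the best state
            p, f = p_best.copy(), f_best
            step *= settings.relaxation
            prev_tg = None
            continue
        if f < f_best:
            p_best, f_best = p.copy(), f
            trace.append({"iteration": it, "step": step, "mse": f, "params": p.copy()})
    return p_best, f_best, trace, converged, it


def _register(fixed, moving, spacing, settings, init, center, model: str) -> RegistrationResult:
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if center is None:
        h, w = fixed.shape
        center = np.array([(w - 1) / 2.0 * spacing, (h - 1) / 2.0 * spacing])
    else:
        center = np.asarray(center, dtype=float)
    if init is None:
        init = AffineTransform2D.identity()
    if model == "rigid":
        to_t = lambda p: _rigid_from_params(p, center)  # noqa: E731
        p0 = _rigid_to_params(init, center)
    else:
        to_t = lambda p: _affine_from_params(p, center)  # noqa: E731
        p0 = _affine_to_params(init, center)
    obj = _MSEObjective(fixed, moving, spacing, to_t)
    p, f, trace, converged, n_it = _regular_step_minimize(obj, p0, settings)
    return RegistrationResult(
        transform=to_t(p), final_mse=f, n_iterations=n_it, converged=converged, trace=trace
    )


def register_rigid_mse(
    fixed: np.ndarray,
    moving: np.ndarray,
    settings: OptimizerSettings | None = None,
    init: AffineTransform2D | None = None,
    *,
    spacing: float = 1.0,
    center: Sequence[float] | None = None,
) -> RegistrationResult:
    """Search the space of 2-D rigid transforms minimising the overlap MSE.

    ``fixed`` and ``moving`` are grayscale rasters sharing ``spacing``
    (μm/px).  The returned transform maps moving-image μm coordinates into
    the fixed frame.  Deterministic for fixed inputs and settings.
    """
    return _register(
        fixed, moving, spacing, settings or low_res_rigid_settings(), init, center, "rigid"
    )


def register_affine_mse(
    fixed: np.ndarray,
    moving: np.ndarray,
    settings: OptimizerSettings | None = None,
    init: AffineTransform2D | None = None,
    *,
    spacing: float = 1.0,
    center: Sequence[float] | None = None,
) -> RegistrationResult:
    """6-parameter affine MSE registration (typically initialised with the
    rigid result)."""
    return _register(
        fixed, moving, spacing, settings or high_res_affine_settings(), init, center, "affine"
    )


# ----------------------------------------------------------------------
# coarse initialisation
# ----------------------------------------------------------------------

def coarse_spacing_for(section: SectionImage, coarse_extents_px: tuple = (172, 264)) -> float:
    """Target spacing that fits the section into the coarse pixel extents."""
    ph, pw = section.extent_um
    sp = max(ph / coarse_extents_px[0], pw / coarse_extents_px[1], section.spacing)
    return float(sp)


def coarse_initialize(
    stack: Sequence[SectionImage],
    settings: OptimizerSettings | None = None,
    coarse_extents_px: tuple = (172, 264),
) -> list:
    """Pairwise low-resolution rigid MSE initialisation of an ordered stack.

    Each adjacent pair is downsampled so the extents fit within
    ``coarse_extents_px``, converted to grayscale, and rigidly registered
    from identity (section ``k+1`` moving onto fixed section ``k``).  Returns
    the N-1 pairwise rigid transforms in μm coordinates, directly applicable
    at full resolution.
    """
    stack = list(stack)
    if len(stack) < 2:
        raise ValueError("need at least 2 sections")
    settings = settings or low_res_rigid_settings()
    sp = coarse_spacing_for(stack[0], coarse_extents_px)
    grays = [to_grayscale(downsample(s, sp)) for s in stack]
    out = []
    for k in range(len(stack) - 1):
        res = register_rigid_mse(grays[k], grays[k + 1], settings, spacing=sp)
        out.append(res.transform)
    return out
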