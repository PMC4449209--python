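"""Rigid and affine 2D transforms in physical (micrometre) coordinates.

Every transform in the package maps 2-D points expressed in micrometres.
Rasters are tied to physical space by their pixel spacing, with the origin at
the centre of pixel (0, 0), x along columns and y along rows.  Keeping the
geometry in physical units makes every distance threshold in the registration
pipeline (candidate gating radius, neighbourhood side, error tolerances)
independent of the scan resolution.

A serial-section reconstruction is a chain of pairwise transforms: entry ``k``
maps section ``k+1`` coordinates into the frame of section ``k``, and the
composed (cumulative) transforms map every section into the frame of section
1, which is the untransformed base of the reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "AffineTransform2D",
    "TransformChain",
    "DegenerateFitError",
    "SingularTransformError",
    "compose",
    "apply_transform",
    "invert",
    "fit_rigid",
    "fit_affine",
    "warp_raster",
]

_DET_TOL = 1e-12
_RIGID_TOL = 1e-6


class DegenerateFitError(ValueError):
    """The point configuration underdetermines the requested transform model."""


class SingularTransformError(ValueError):
    """The linear part of a transform is not invertible."""


@dataclass(frozen=True, eq=False)
class AffineTransform2D:
    """A 2-D affine map ``x -> matrix @ x + translation`` in micrometres.

    Parameters
    ----------
    matrix
        2x2 dimensionless linear part.
    translation
        2-vector in micrometres, ordered (x, y).
    is_rigid_constrained
        If True the linear part must be a proper rotation (orthogonal,
        determinant +1); rigid transforms are the "rotation and translation"
        model used to initialise the registration cascade.
    """

    matrix: np.ndarray
    translation: np.ndarray
    is_rigid_constrained: bool = False

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float).reshape(2, 2)
        t = np.array(self.translation, dtype=float).reshape(2)
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(t))):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)
        m.setflags(write=False)
        t.setflags(write=False)
        if self.is_rigid_constrained:
            if not np.allclose(m.T @ m, np.eye(2), atol=_RIGID_TOL) or np.linalg.det(m) < 0:
                raise ValueError(
                    "rigid-constrained transform requires an orthogonal linear "
                    "part with determinant +1"
                )

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), is_rigid_constrained=True)

    @classmethod
    def from_rotation(
        cls,
        theta: float,
        center: Sequence[float] | None = None,
        translation: Sequence[float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Rotation by ``theta`` radians about ``center`` (default the origin),
        followed by ``translation`` (μm)."""
        c, s = np.cos(theta), np.sin(theta)
        m = np.array([[c, -s], [s, c]])
        t = np.asarray(translation, dtype=float)
        if center is not None:
            cen = np.asarray(center, dtype=float)
            t = t + cen - m @ cen
        return cls(m, t, is_rigid_constrained=True)

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        return cls(np.eye(2), (tx, ty), is_rigid_constrained=True)

    @classmethod
    def from_homogeneous(cls, h: np.ndarray, is_rigid_constrained: bool = False) -> "AffineTransform2D":
        h = np.asarray(h, dtype=float).reshape(3, 3)
        if not np.allclose(h[2], [0.0, 0.0, 1.0]):
            raise ValueError("last row of a 2D homogeneous matrix must be [0, 0, 1]")
        return cls(h[:2, :2], h[:2, 2], is_rigid_constrained=is_rigid_constrained)

    # ------------------------------------------------------------------
    # algebra
    # ------------------------------------------------------------------
    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))

    def homogeneous(self) -> np.ndarray:
        h = np.eye(3)
        h[:2, :2] = self.matrix
        h[:2, 2] = self.translation
        return h

    def apply(self, points: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
        """Map points (n, 2) or a single 2-vector through the transform (μm in,
        μm out)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix.T + self.translation
        return out[0] if single else out

    __call__ = apply

    def invert(self) -> "AffineTransform2D":
        if abs(self.det) <= _DET_TOL:
            raise SingularTransformError(f"transform is singular (det={self.det:g})")
        minv = np.linalg.inv(self.matrix)
        return AffineTransform2D(
            minv, -minv @ self.translation, is_rigid_constrained=self.is_rigid_constrained
        )

    def almost_equals(self, other: "AffineTransform2D", atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.matrix, other.matrix, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # ------------------------------------------------------------------
    # serialisation: 3x3 homogeneous matrix, row-major, spacing units μm
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "homogeneous": self.homogeneous().tolist(),
            "units": "um",
            "is_rigid_constrained": bool(self.is_rigid_constrained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        if d.get("units", "um") != "um":
            raise ValueError(f"unsupported units {d['units']!r}")
        return cls.from_homogeneous(
            np.asarray(d["homogeneous"]), is_rigid_constrained=bool(d.get("is_rigid_constrained", False))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "rigid" if self.is_rigid_constrained else "affine"
        return (
            f"AffineTransform2D({kind}, matrix={np.array2string(self.matrix, precision=4)}, "
            f"t={np.array2string(self.translation, precision=3)} um)"
        )


def compose(outer: AffineTransform2D, inner: AffineTransform2D) -> AffineTransform2D:
    """Return the transform mapping ``x -> outer(inner(x))``.

    The result is flagged rigid iff both inputs are rigid (a composition of
    rotations+translations is again a rotation+translation).
    """
    m = outer.matrix @ inner.matrix
    t = outer.matrix @ inner.translation + outer.translation
    return AffineTransform2D(
        m, t, is_rigid_constrained=outer.is_rigid_constrained and inner.is_rigid_constrained
    )


def apply_transform(t: AffineTransform2D, points) -> np.ndarray:
    return t.apply(points)


def invert(t: AffineTransform2D) -> AffineTransform2D:
    return t.invert()


# ----------------------------------------------------------------------
# Point-set fitting
# ----------------------------------------------------------------------

def _as_point_arrays(src, dst, minimum: int):
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    if len(src) < minimum:
        raise DegenerateFitError(f"need at least {minimum} point pairs, got {len(src)}")
    return src, dst


def fit_rigid(src, dst) -> AffineTransform2D:
    """Least-squares rotation + translation mapping ``src`` onto ``dst``.

    Minimises ``sum ||R src_i + t - dst_i||^2`` over proper rotations R
    (no scaling, no reflection).  Uses the closed-form 2-D solution: after
    centring, the optimal angle is ``atan2(sum cross, sum dot)``, which is the
    det=+1 Procrustes solution.  Deterministic.
    """
    src, dst = _as_point_arrays(src, dst, minimum=2)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    if np.max(np.abs(xs)) < 1e-12:
        raise DegenerateFitError("all source points coincide; rotation is underdetermined")
    cross = float(np.sum(xs[:, 0] * xd[:, 1] - xs[:, 1] * xd[:, 0]))
    dot = float(np.sum(xs * xd))
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    r = np.array([[c, -s], [s, c]])
    t = mu_d - r @ mu_s
    return AffineTransform2D(r, t, is_rigid_constrained=True)


def fit_affine(src, dst) -> AffineTransform2D:
    """Ordinary least-squares affine map of ``src`` onto ``dst``.

    For exactly three non-collinear pairs the fit interpolates (residual 0);
    collinear configurations raise :class:`DegenerateFitError`.
    """
    src, dst = _as_point_arrays(src, dst, minimum=3)
    centred = src - src.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] <= 1e-9 * max(1.0, sv[0]):
        raise DegenerateFitError("source points are (nearly) collinear; affine fit is underdetermined")
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform2D(coef[:2].T, coef[2], is_rigid_constrained=False)


# ----------------------------------------------------------------------
# Transform chains
# ----------------------------------------------------------------------

@dataclass
class TransformChain:
    """Ordered pairwise transforms of an N-section stack.

    ``pairwise[k]`` (0-based list index) maps section ``k+2`` coordinates into
    the frame of section ``k+1``.  ``cumulative[k]`` maps section ``k+1`` into
    the frame of section 1; ``cumulative[0]`` is the identity.
    """

    pairwise: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairwise = list(self.pairwise)
        for t in self.pairwise:
            if not isinstance(t, AffineTransform2D):
                raise TypeError("pairwise entries must be AffineTransform2D")

    @property
    def n_sections(self) -> int:
        return len(self.pairwise) + 1

    @property
    def cumulative(self) -> list:
        out = [AffineTransform2D.identity()]
        for t in self.pairwise:
            out.append(compose(out[-1], t))
        return out

    def map_to_reference(self, section_index: int, points) -> np.ndarray:
        """Map points from the frame of 1-based ``section_index`` into the
        frame of section 1."""
        if not 1 <= section_index <= self.n_sections:
            raise IndexError(f"section {section_index} outside chain of {self.n_sections}")
        return self.cumulative[section_index - 1].apply(points)

    def to_json(self, path) -> None:
        payload = {"units": "um", "pairwise": [t.to_dict() for t in self.pairwise]}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "TransformChain":
        payload = json.loads(Path(path).read_text())
        return cls([AffineTransform2D.from_dict(d) for d in payload["pairwise"]])


# ----------------------------------------------------------------------
# Array-level backward warping
# ----------------------------------------------------------------------

def warp_raster(
    raster: np.ndarray,
    t: AffineTransform2D,
    *,
    in_spacing: float,
    out_spacing: float | None = None,
    out_shape: tuple | None = None,
    out_origin: Sequence[float] = (0.0, 0.0),
    fill: float = 255.0,
) -> np.ndarray:
    """Backward (pull) warp of a 2-D raster through ``t`` with bilinear
    interpolation.

    The output pixel at physical location ``x`` takes the bilinearly
    interpolated value of the input at ``t^{-1}(x)``; locations outside the
    input domain are filled with ``fill`` (slide-background white by default).
    ``out_origin`` is the physical location (x, y) in μm of the centre of
    output pixel (0, 0).
    """
    if out_spacing is None:
        out_spacing = in_spacing
    if out_shape is None:
        out_shape = raster.shape[:2]
    inv = t.invert()
    h, w = int(out_shape[0]), int(out_shape[1])
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    phys = np.column_stack(
        [
            out_origin[0] + cols.ravel() * out_spacing,
            out_origin[1] + rows.ravel() * out_spacing,
        ]
    )
    src = inv.apply(phys)
    # pixel coordinates (row, col) in the input raster
    coords = np.vstack([src[:, 1] / in_spacing, src[:, 0] / in_spacing])
    out = ndimage.map_coordinates(
        np.asarray(raster, dtype=float), coords, order=1, mode="constant", cval=fill
    )
    return out.reshape(h, w)
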