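"""Full reconstruction cascade: coarse init → branch refinement → composition
→ volume rendering.

Both the intensity branch and the nucleus-landmark branch consume the same
coarse low-resolution rigid initialisation; the pairwise transforms they
produce are composed into cumulative transforms anchored at section 1 (the
untransformed base), and the full-resolution RGB sections are resampled onto
a common union grid and stacked into a voxel volume with slice spacing equal
to the section thickness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from . import landmarks as lmk
from .geometry import AffineTransform2D, TransformChain, compose
from .image import SectionImage, downsample, resample_image, to_grayscale
from .intensity import (
    OptimizerSettings,
    coarse_initialize,
    high_res_affine_settings,
    high_res_rigid_settings,
    low_res_rigid_settings,
    register_affine_mse,
    register_rigid_mse,
)

__all__ = [
    "METHODS",
    "ReconstructionConfig",
    "ReconstructionResult",
    "reconstruct",
    "render_volume",
    "write_volume",
    "read_volume",
    "vessel_centroid_baseline",
]

METHODS = ("intensity_rigid", "intensity_affine", "nucleus_rigid", "nucleus_affine")


@dataclass
class ReconstructionConfig:
    """Tunable parameters of the cascade (all physical units are μm)."""

    downsample_spacing_um: float = 4.0
    coarse_extents_px: tuple = (172, 264)
    green_threshold_frac: float = lmk.GREEN_THRESHOLD_FRAC
    area_min_um2: float = lmk.AREA_MIN_UM2
    area_max_um2: float = lmk.AREA_MAX_UM2
    dilation_radius_um: float = lmk.DILATION_RADIUS_UM
    bg_mean_frac: float = lmk.BG_MEAN_FRAC
    bg_sd_frac: float = lmk.BG_SD_FRAC
    neighborhood_side_um: float = lmk.NEIGHBORHOOD_SIDE_UM
    window: float = lmk.WINDOW
    level: float = lmk.LEVEL
    gate_T_um: float = lmk.GATE_T_UM
    top_k: int = lmk.TOP_K
    low_res: OptimizerSettings = field(default_factory=low_res_rigid_settings)
    high_res_rigid: OptimizerSettings = field(default_factory=high_res_rigid_settings)
    high_res_affine: OptimizerSettings = field(default_factory=high_res_affine_settings)


@dataclass
class PairDiagnostics:
    fixed_index: int
    moving_index: int
    n_landmarks_fixed: int = 0
    n_landmarks_moving: int = 0
    n_matched: int = 0
    n_selected: int = 0
    mean_selected_score: float = float("nan")


@dataclass
class ReconstructionResult:
    """Transform chain plus volume geometry and per-pair diagnostics."""

    chain: TransformChain
    method: str
    spacing: float
    thickness: float
    coarse: list = field(default_factory=list, repr=False)
    diagnostics: list = field(default_factory=list, repr=False)

    @property
    def voxel_spacing(self) -> tuple:
        """(in-plane, in-plane, thickness) in μm."""
        return (self.spacing, self.spacing, self.thickness)

    def summary(self) -> str:
        lines = [
            f"histo3d reconstruction ({self.method})",
            f"  sections: {self.chain.n_sections}",
            f"  voxel spacing: {self.voxel_spacing} um",
        ]
        for k, t in enumerate(self.chain.pairwise, start=1):
            theta = math.degrees(math.atan2(t.matrix[1, 0], t.matrix[0, 0]))
            lines.append(
                f"  pair {k + 1}->{k}: rot {theta:+.2f} deg, "
                f"t ({t.translation[0]:+.1f}, {t.translation[1]:+.1f}) um"
            )
        for d in self.diagnostics:
            if d.n_matched:
                lines.append(
                    f"  pair {d.moving_index}->{d.fixed_index}: "
                    f"{d.n_landmarks_fixed}/{d.n_landmarks_moving} landmarks, "
                    f"{d.n_matched} matched, {d.n_selected} selected "
                    f"(mean MSE {d.mean_selected_score:.1f})"
                )
        return "\n".join(lines)


def _validate_stack(stack: Sequence[SectionImage]) -> None:
    if len(stack) < 2:
        raise ValueError("need at least 2 sections to reconstruct")
    sp = stack[0].spacing
    for i, s in enumerate(stack):
        if s.spacing != sp:
            raise ValueError("sections must share pixel spacing")
        if s.index != i + 1:
            raise ValueError("section indices must be contiguous from 1")


def _nucleus_landmarks(section: SectionImage, config: ReconstructionConfig) -> list:
    lms = lmk.segment_nuclei(
        section, config.green_threshold_frac, config.area_min_um2, config.area_max_um2
    )
    return lmk.filter_debris(
        lms, section, config.dilation_radius_um, config.bg_mean_frac, config.bg_sd_frac
    )


def reconstruct(
    stack: Sequence[SectionImage],
    method: str = "nucleus_affine",
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Run the selected registration cascade over an ordered stack.

    Every method starts from the shared coarse low-resolution rigid
    initialisation.  The intensity branch refines each pair by rigid (then
    affine) MSE descent on 4 μm/px grayscale images; the nucleus branch
    segments, debris-filters, matches and fits landmarks.  Deterministic
    given the inputs and config.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    config = config or ReconstructionConfig()
    stack = list(stack)
    _validate_stack(stack)
    coarse = coarse_initialize(stack, config.low_res, config.coarse_extents_px)

    pairwise: list = []
    diagnostics: list = []
    if method.startswith("intensity"):
        ds = [downsample(s, max(config.downsample_spacing_um, s.spacing)) for s in stack]
        grays = [to_grayscale(d) for d in ds]
        sp = ds[0].spacing
        for k in range(len(stack) - 1):
            rig = register_rigid_mse(
                grays[k], grays[k + 1], config.high_res_rigid, init=coarse[k], spacing=sp
            )
            t = rig.transform
            if method == "intensity_affine":
                aff = register_affine_mse(
                    grays[k], grays[k + 1], config.high_res_affine, init=t, spacing=sp
                )
                t = aff.transform
            pairwise.append(t)
            diagnostics.append(PairDiagnostics(fixed_index=k + 1, moving_index=k + 2))
    else:
        model = "affine" if method == "nucleus_affine" else "rigid"
        lms = [_nucleus_landmarks(s, config) for s in stack]
        for k in range(len(stack) - 1):
            cset = lmk.match_nuclei(
                lms[k], lms[k + 1], stack[k], stack[k + 1], coarse[k],
                config.gate_T_um, config.neighborhood_side_um, config.window, config.level,
            )
            try:
                best = lmk.select_best_correspondences(cset, config.top_k)
                t = lmk.register_landmarks(best, model)
            except lmk.UnregistrablePairError as exc:
                raise lmk.UnregistrablePairError(
                    f"pair ({k + 1}, {k + 2}) is unregistrable: {exc}"
                ) from exc
            pairwise.append(t)
            diagnostics.append(
                PairDiagnostics(
                    fixed_index=k + 1,
                    moving_index=k + 2,
                    n_landmarks_fixed=len(lms[k]),
                    n_landmarks_moving=len(lms[k + 1]),
                    n_matched=len(cset),
                    n_selected=len(best),
                    mean_selected_score=float(best.scores().mean()),
                )
            )
    return ReconstructionResult(
        chain=TransformChain(pairwise),
        method=method,
        spacing=stack[0].spacing,
        thickness=stack[0].thickness,
        coarse=coarse,
        diagnostics=diagnostics,
    )


# ----------------------------------------------------------------------
# volume rendering
# ----------------------------------------------------------------------

def _union_grid(stack: Sequence[SectionImage], chain: TransformChain):
    """Bounding grid of all transformed section footprints, snapped to the
    section-1 pixel grid so the base slice is reproduced bit-exactly."""
    sp = stack[0].spacing
    mins = np.array([np.inf, np.inf])
    maxs = -np.array([np.inf, np.inf])
    for s, t in zip(stack, chain.cumulative):
        h, w = s.shape
        corners = np.array(
            [[0, 0], [(w - 1) * sp, 0], [0, (h - 1) * sp], [(w - 1) * sp, (h - 1) * sp]]
        )
        mapped = t.apply(corners)
        mins = np.minimum(mins, mapped.min(axis=0))
        maxs = np.maximum(maxs, mapped.max(axis=0))
    origin = np.floor(mins / sp) * sp
    out_w = int(math.ceil((maxs[0] - origin[0]) / sp)) + 1
    out_h = int(math.ceil((maxs[1] - origin[1]) / sp)) + 1
    return origin, (out_h, out_w)


def render_volume(stack: Sequence[SectionImage], result: ReconstructionResult):
    """Resample every full-resolution section into the section-1 frame on a
    common union grid and stack along z.

    Returns ``(volume, geometry)`` where volume is (N, H, W, 3) uint8 and
    geometry records the voxel spacing (μm) and the grid origin.
    """
    stack = list(stack)
    chain = result.chain
    if chain.n_sections != len(stack):
        raise ValueError("chain does not cover the stack")
    origin, (out_h, out_w) = _union_grid(stack, chain)
    vol = np.empty((len(stack), out_h, out_w, 3), dtype=np.uint8)
    for i, (s, t) in enumerate(zip(stack, chain.cumulative)):
        # resample with the inverse cumulative: slice(x) = section(t^{-1}(x))
        warped = resample_image(
            s, t, out_shape=(out_h, out_w), out_origin=origin
        )
        vol[i] = warped.pixels
    geometry = {
        "voxel_spacing_um": [result.spacing, result.spacing, result.thickness],
        "origin_um": [float(origin[0]), float(origin[1])],
        "n_sections": len(stack),
    }
    return vol, geometry


def write_volume(volume: np.ndarray, path, geometry: dict | None = None) -> None:
    """Write a multipage TIFF (one RGB page per section) plus a JSON sidecar
    recording the voxel spacing in μm."""
    path = Path(path)
    try:
        tifffile.imwrite(str(path), volume, photometric="rgb")
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    sidecar = dict(geometry or {})
    sidecar.setdefault("units", "um")
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_volume(path) -> np.ndarray:
    return tifffile.imread(str(path))


# ----------------------------------------------------------------------
# naive baseline for the banana-into-cylinder comparison
# ----------------------------------------------------------------------

def vessel_centroid_baseline(stack: Sequence[SectionImage]) -> TransformChain:
    """Deliberately naive reconstruction: translate each section so its
    vessel-wall centroid lands on its neighbour's.

    This is the salient-structure pairwise alignment that straightens
    obliquely oriented vessels into section-orthogonal cylinders — the
    failure mode the nucleus-landmark method avoids.
    """
    from .phantom import detect_vessel_centroids

    cents = detect_vessel_centroids(stack)
    pairwise = []
    for k in range(1, len(stack)):
        c_fixed, c_moving = cents.get(k), cents.get(k + 1)
        if c_fixed is None or c_moving is None:
            raise ValueError(f"no vessel visible on pair ({k}, {k + 1})")
        d = c_fixed - c_moving
        pairwise.append(AffineTransform2D.from_translation(d[0], d[1]))
    return TransformChain(pairwise)
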