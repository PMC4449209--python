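"""Bisected-nucleus landmark extraction, correspondence, and registration.

Cell nuclei are roughly 5 μm in diameter — about one section thickness — so
a nucleus cut by the microtome blade appears at homologous positions on
exactly two adjacent sections and on no others.  Their centroids therefore
make unbiased point landmarks for pairwise registration, unlike vessel cross
sections whose centre-to-centre vectors are coherent across many sections
and get straightened ("banana into cylinder") by salient-structure
alignment.

The pipeline on each adjacent pair:

1. segment nuclei on both sections by colour (green channel below 80% of
   255, i.e. hematoxylin-dark) and area (6–160 μm²);
2. reject debris lying on the blank glass outside the tissue (surroundings
   within a 5 μm dilation look background-like: mean green > 95%, SD < 4%);
3. for each nucleus p on section I, gather candidate nuclei on section J
   whose initialisation-mapped centroids lie within T = 100 μm of p, and
   pick the candidate whose 250 μm window/levelled green-channel
   neighbourhood has the smallest MSE against p's neighbourhood;
4. keep the 100 correspondences with the best (smallest) MSE — most nuclei
   are not bisected, so only the strongest matches define the fit;
5. fit a rigid (or affine) transform to the surviving pairs and compose it
   with the initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure, morphology

from . import geometry
from .geometry import AffineTransform2D, compose
from .image import SectionImage, mse, window_level

__all__ = [
    "NucleusLandmark",
    "CorrespondencePair",
    "CorrespondenceSet",
    "UnregistrablePairError",
    "segment_nuclei",
    "filter_debris",
    "extract_neighborhood",
    "match_nuclei",
    "select_best_correspondences",
    "register_landmarks",
    "landmarks_to_dataframe",
]

GREEN_THRESHOLD_FRAC = 0.80
AREA_MIN_UM2 = 6.0
AREA_MAX_UM2 = 160.0
DILATION_RADIUS_UM = 5.0
BG_MEAN_FRAC = 0.95
BG_SD_FRAC = 0.04
NEIGHBORHOOD_SIDE_UM = 250.0
WINDOW = 14.0
LEVEL = 235.0
GATE_T_UM = 100.0
TOP_K = 100


class UnregistrablePairError(RuntimeError):
    """Too few surviving correspondences to fit the requested model."""


@dataclass(frozen=True, eq=False)
class NucleusLandmark:
    """A segmented nucleus centroid in section-local μm coordinates."""

    centroid: np.ndarray  # (x, y) μm
    area: float  # μm²
    section_index: int
    _pixels: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float).reshape(2)
        c.setflags(write=False)
        object.__setattr__(self, "centroid", c)


@dataclass(frozen=True)
class CorrespondencePair:
    """A scored match p -> p' between adjacent sections; the score is the
    neighbourhood MSE (intensity², lower = more similar surroundings)."""

    p: NucleusLandmark
    p_prime: NucleusLandmark
    score: float


@dataclass
class CorrespondenceSet:
    """Scored candidate matches between one adjacent section pair, together
    with the initialisation transform the gating was performed under."""

    pairs: list
    init: AffineTransform2D
    gate_T_um: float = GATE_T_UM
    section_pair: tuple = (0, 0)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def scores(self) -> np.ndarray:
        return np.array([c.score for c in self.pairs])

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "section_index": c.p.section_index,
                "x_um": c.p.centroid[0],
                "y_um": c.p.centroid[1],
                "matched_section_index": c.p_prime.section_index,
                "matched_x_um": c.p_prime.centroid[0],
                "matched_y_um": c.p_prime.centroid[1],
                "score": c.score,
            }
            for c in self.pairs
        ]
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def segment_nuclei(
    section: SectionImage,
    green_threshold_frac: float = GREEN_THRESHOLD_FRAC,
    area_min_um2: float = AREA_MIN_UM2,
    area_max_um2: float = AREA_MAX_UM2,
) -> list:
    """Detect nuclei as hematoxylin-dark connected components.

    A pixel is nucleus-candidate if its green channel is below
    ``green_threshold_frac`` of 255; 8-connected components whose physical
    area lies in [6, 160] μm² become landmarks at their centroids.  Both the
    colour and the area criterion must be met.
    """
    sp = section.spacing
    mask = section.pixels[:, :, 1] < green_threshold_frac * 255.0
    labels = measure.label(mask, connectivity=2)
    px_area = sp * sp
    out = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if not (area_min_um2 <= area <= area_max_um2):
            continue
        r, c = region.centroid
        coords = region.coords
        out.append(
            NucleusLandmark(
                centroid=(c * sp, r * sp),
                area=float(area),
                section_index=section.index,
                _pixels=(coords[:, 0].copy(), coords[:, 1].copy()),
            )
        )
    return out


def filter_debris(
    landmarks: Sequence[NucleusLandmark],
    section: SectionImage,
    dilation_radius_um: float = DILATION_RADIUS_UM,
    bg_mean_frac: float = BG_MEAN_FRAC,
    bg_sd_frac: float = BG_SD_FRAC,
) -> list:
    """Drop detections whose surroundings look like blank glass slide.

    Each component is dilated by a 5 μm disk; the mean and standard deviation
    of the green channel over the dilated ring (dilation minus component,
    clipped to the image) are compared to the background criteria.  A
    landmark is discarded iff mean > 95% of 255 AND SD < 4% of 255.
    """
    sp = section.spacing
    r_px = max(1, int(round(dilation_radius_um / sp)))
    selem = morphology.disk(r_px)
    green = section.pixels[:, :, 1].astype(float)
    h, w = green.shape
    mean_cut = bg_mean_frac * 255.0
    sd_cut = bg_sd_frac * 255.0
    kept = []
    for lm in landmarks:
        if lm._pixels is None:
            raise ValueError("landmark lacks component pixels; run segment_nuclei first")
        rows, cols = lm._pixels
        r0 = max(0, rows.min() - r_px)
        r1 = min(h, rows.max() + r_px + 1)
        c0 = max(0, cols.min() - r_px)
        c1 = min(w, cols.max() + r_px + 1)
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[rows - r0, cols - c0] = True
        ring = morphology.dilation(local, selem) & ~local
        vals = green[r0:r1, c0:c1][ring]
        if vals.size == 0:
            kept.append(lm)
            continue
        if vals.mean() > mean_cut and vals.std() < sd_cut:
            continue  # background-like surroundings: debris on glass
        kept.append(lm)
    return kept


# ----------------------------------------------------------------------
# neighbourhoods and matching
# ----------------------------------------------------------------------

def extract_neighborhood(
    section: SectionImage,
    center: Sequence[float],
    side_um: float = NEIGHBORHOOD_SIDE_UM,
    window: float = WINDOW,
    level: float = LEVEL,
) -> np.ndarray:
    """Axis-aligned square of the window/levelled green channel centred on a
    physical point; regions outside the image are padded white."""
    if not side_um > 0:
        raise ValueError("side must be positive")
    sp = section.spacing
    n = int(round(side_um / sp))
    half = n // 2
    cx = int(round(center[0] / sp))
    cy = int(round(center[1] / sp))
    r0, c0 = cy - half, cx - half
    r1, c1 = r0 + n, c0 + n
    h, w = section.shape
    patch = np.full((n, n), 255.0)
    ri0, ri1 = max(r0, 0), min(r1, h)
    ci0, ci1 = max(c0, 0), min(c1, w)
    if ri0 < ri1 and ci0 < ci1:
        patch[ri0 - r0 : ri1 - r0, ci0 - c0 : ci1 - c0] = section.pixels[ri0:ri1, ci0:ci1, 1]
    return window_level(patch, window, level).astype(np.uint8)


def match_nuclei(
    landmarks_I: Sequence[NucleusLandmark],
    landmarks_J: Sequence[NucleusLandmark],
    section_I: SectionImage,
    section_J: SectionImage,
    init: AffineTransform2D,
    gate_T_um: float = GATE_T_UM,
    side_um: float = NEIGHBORHOOD_SIDE_UM,
    window: float = WINDOW,
    level: float = LEVEL,
) -> CorrespondenceSet:
    """Block-matching correspondence of nuclei across an adjacent pair.

    ``init`` maps section-J coordinates into section I's frame (the coarse
    initialisation); candidates are the J nuclei whose mapped centroids lie
    within ``gate_T_um`` of p, and the match is the candidate minimising the
    neighbourhood MSE.  Nuclei with no candidate yield no pair.  Many-to-one
    matches are permitted.
    """
    pairs: list = []
    cset = CorrespondenceSet(
        pairs, init=init, gate_T_um=gate_T_um,
        section_pair=(section_I.index, section_J.index),
    )
    if not landmarks_I or not landmarks_J:
        return cset
    mapped_J = init.apply(np.array([lm.centroid for lm in landmarks_J]))
    tree = cKDTree(mapped_J)
    cache_J: dict = {}

    def nb_J(j: int) -> np.ndarray:
        if j not in cache_J:
            cache_J[j] = extract_neighborhood(
                section_J, landmarks_J[j].centroid, side_um, window, level
            ).astype(np.float32)
        return cache_J[j]

    for lm in landmarks_I:
        cand = tree.query_ball_point(lm.centroid, gate_T_um)
        if not cand:
            continue
        nb_p = extract_neighborhood(section_I, lm.centroid, side_um, window, level).astype(
            np.float32
        )
        best_j, best_score = -1, np.inf
        for j in cand:
            d = nb_p - nb_J(j)
            score = float(np.mean(d * d))
            if score < best_score:
                best_j, best_score = j, score
        pairs.append(CorrespondencePair(p=lm, p_prime=landmarks_J[best_j], score=best_score))
    return cset


def select_best_correspondences(cset: CorrespondenceSet, k: int = TOP_K) -> CorrespondenceSet:
    """Keep the min(k, n) pairs with the smallest neighbourhood MSE.

    Ties at the cutoff are broken deterministically by (score, p's y, p's x).
    Raises :class:`UnregistrablePairError` when fewer than 2 pairs survive
    (no transform model is fittable from fewer).
    """
    order = sorted(
        range(len(cset.pairs)),
        key=lambda i: (
            cset.pairs[i].score,
            cset.pairs[i].p.centroid[1],
            cset.pairs[i].p.centroid[0],
        ),
    )
    selected = [cset.pairs[i] for i in order[: min(k, len(order))]]
    if len(selected) < 2:
        raise UnregistrablePairError(
            f"section pair {cset.section_pair}: only {len(selected)} correspondences"
        )
    return replace(cset, pairs=selected)


def register_landmarks(cset: CorrespondenceSet, model: str = "rigid") -> AffineTransform2D:
    """Fit a transform to the selected correspondences and compose it with
    the initialisation.

    The fit maps init-mapped p' positions onto p positions, so the returned
    transform maps raw section-J μm coordinates into section I's frame.
    """
    if model not in ("rigid", "affine"):
        raise ValueError(f"unknown model {model!r}")
    if len(cset.pairs) == 0:
        raise UnregistrablePairError(f"section pair {cset.section_pair}: no correspondences")
    src = cset.init.apply(np.array([c.p_prime.centroid for c in cset.pairs]))
    dst = np.array([c.p.centroid for c in cset.pairs])
    try:
        if model == "rigid":
            fit = geometry.fit_rigid(src, dst)
        else:
            fit = geometry.fit_affine(src, dst)
    except geometry.DegenerateFitError as exc:
        raise UnregistrablePairError(
            f"section pair {cset.section_pair}: degenerate correspondence geometry ({exc})"
        ) from exc
    return compose(fit, cset.init)


# ----------------------------------------------------------------------
# serialisation
# ----------------------------------------------------------------------

def landmarks_to_dataframe(landmarks: Sequence[NucleusLandmark]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "section_index": lm.section_index,
                "x_um": lm.centroid[0],
                "y_um": lm.centroid[1],
                "area_um2": lm.area,
            }
            for lm in landmarks
        ]
    )
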