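"""Synthetic serial-section phantom with exact ground truth.

The generator emulates the optical structure the registration method
assumes: a white glass-slide background, an elliptical tissue footprint with
low-amplitude smooth texture, brown (DAB-like) vessel walls following 3-D
centerlines at known inclinations, and blue (hematoxylin-like) nuclei
~5 μm in diameter placed uniformly in the 3-D slab.  Nucleus diameters are
kept at or below the section thickness so every nucleus is bisected by at
most one cutting plane and a homologous landmark pair appears on exactly two
adjacent sections.

Each section renders the intersection of the 3-D scene with its 5 μm slab in
an unperturbed world frame, then applies the inverse of that section's
ground-truth rigid/affine perturbation, so registration must recover the
perturbations.  Everything is reproducible from the seed, and the ground
truth records the true transform chain, all nucleus positions, the
homologous pair list with its registration/reference split, and the vessel
centerline per section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import AffineTransform2D, TransformChain, compose
from .image import SectionImage, resample_image, round_half_up

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "ground_truth_pairs",
    "vessel_axis_angle",
    "detect_vessel_centroids",
]

# stain colours (R, G, B).  The tissue base green (222) sits safely between
# the 80% (=204) nucleus colour threshold and the 95%-of-255 glass criterion
# of the debris filter; the pale interstitial blobs (green 240) land inside
# the 14/235 window/level ramp, giving the neighbourhood matcher the
# fine-scale in-band structure that pale fibre boundaries provide in real
# transversely sectioned muscle.
COLOR_BACKGROUND = (255.0, 255.0, 255.0)
COLOR_TISSUE = (234.0, 222.0, 228.0)
COLOR_INTERSTITIAL = (242.0, 234.0, 238.0)
COLOR_NUCLEUS = (95.0, 128.0, 196.0)  # green ≈ 50% of 255
COLOR_VESSEL = (150.0, 92.0, 50.0)

# a ground-truth landmark counts as detectable when its cut-disk area
# reaches 9 μm² — the segmenter's 6 μm² floor plus a rasterisation margin
DETECTABLE_AREA_UM2 = 9.0


@dataclass(frozen=True)
class VesselSpec:
    """A straight vessel: centerline through ``anchor_um`` (x, y at z=0),
    inclined ``inclination_deg`` to the z-axis along azimuth
    ``azimuth_deg``, with a DAB-stained wall annulus."""

    anchor_um: tuple = (0.0, 0.0)
    inclination_deg: float = 30.0
    azimuth_deg: float = 0.0
    inner_radius_um: float = 10.0
    outer_radius_um: float = 16.0

    def center_at(self, z: float) -> np.ndarray:
        drift = math.tan(math.radians(self.inclination_deg)) * z
        az = math.radians(self.azimuth_deg)
        return np.array(
            [self.anchor_um[0] + drift * math.cos(az), self.anchor_um[1] + drift * math.sin(az)]
        )


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic stack.

    Defaults give a 2 x 2 mm footprint at 1 μm/pixel, ten 5 μm sections,
    300 nuclei per mm² per section-slab with diameters near 5 μm, one vessel
    inclined 30° to the section normal, and independent per-section rigid
    perturbations up to 50 μm / 5°.
    """

    n_sections: int = 10
    extents_um: tuple = (2000.0, 2000.0)  # (height/y, width/x)
    pixel_spacing_um: float = 1.0
    section_thickness_um: float = 5.0
    nucleus_density_per_mm2: float = 400.0
    nucleus_diameter_mean_um: float = 5.0
    nucleus_diameter_sd_um: float = 0.7
    nucleus_diameter_range_um: tuple = (3.2, 5.0)
    vessels: tuple = None  # default: one 30° vessel through the centre
    max_translation_um: float = 50.0
    max_rotation_deg: float = 5.0
    affine_deviation: float = 0.0  # max |shear/scale| deviation of the linear part
    tissue_margin_um: float = 150.0
    boundary_lobe_amps: tuple = (0.12, 0.08)  # outward 2nd/3rd-harmonic lobes
    interstitial_coverage: float = 0.35
    interstitial_radius_um: tuple = (3.0, 25.0)
    texture_shared_amp: float = 4.0
    texture_section_amp: float = 2.5
    texture_shared_sigma_um: float = 25.0
    texture_section_sigma_um: float = 10.0
    noise_sd: float = 2.0
    reference_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be positive")
        if self.nucleus_density_per_mm2 <= 0:
            raise ValueError("nucleus density must be positive")
        if self.pixel_spacing_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.vessels is None:
            cy, cx = self.extents_um[0] / 2.0, self.extents_um[1] / 2.0
            # anchor offset so the inclined vessel stays near the centre mid-stack
            depth = self.n_sections * self.section_thickness_um
            drift = math.tan(math.radians(30.0)) * depth / 2.0
            self.vessels = (
                VesselSpec(anchor_um=(cx - drift, cy), inclination_deg=30.0, azimuth_deg=0.0),
            )
        self.vessels = tuple(self.vessels)
        lo, hi = self.nucleus_diameter_range_um
        if hi > 2.0 * self.section_thickness_um:
            raise ValueError("nucleus diameters must not exceed twice the section thickness")

    @property
    def ellipse_center(self) -> np.ndarray:
        return np.array([self.extents_um[1] / 2.0, self.extents_um[0] / 2.0])  # (x, y)

    @property
    def ellipse_semiaxes(self) -> np.ndarray:
        return np.array(
            [
                self.extents_um[1] / 2.0 - self.tissue_margin_um,
                self.extents_um[0] / 2.0 - self.tissue_margin_um,
            ]
        )  # (x, y)

    @property
    def tissue_area_mm2(self) -> float:
        a, b = self.ellipse_semiaxes
        return float(math.pi * a * b / 1e6)


@dataclass
class PhantomGroundTruth:
    """Exact truth for one generated stack."""

    spec: PhantomSpec
    section_transforms: list  # S_k: world μm -> rendered section-k μm (S_1 = identity)
    chain: TransformChain  # true pairwise transforms (section k+1 -> k)
    nucleus_centers: np.ndarray  # (n, 3) world μm
    nucleus_diameters: np.ndarray  # (n,)
    landmarks: dict  # section -> {"ids": array, "world": (m,2), "rendered": (m,2), "area": (m,)}
    pairs: list  # homologous pairs: dicts with keys section, nucleus_id, p_I, p_J (rendered μm)
    split: dict  # nucleus_id -> "registration" | "reference"
    vessel_centroids_world: dict  # section -> (x, y) of the first vessel's centerline
    vessel_centroids_rendered: dict

    @property
    def cumulative(self) -> list:
        return self.chain.cumulative


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_px, amplitude) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_px)
    sd = f.std()
    if sd > 0:
        f *= amplitude / sd
    return f


def _draw_disk(img: np.ndarray, cx: float, cy: float, radius: float, color, spacing: float):
    """Paint a filled disk (physical μm coords) into an (H, W, 3) float image."""
    h, w = img.shape[:2]
    r_px = radius / spacing
    c0 = max(0, int(math.floor((cx / spacing) - r_px - 1)))
    c1 = min(w, int(math.ceil((cx / spacing) + r_px + 2)))
    r0 = max(0, int(math.floor((cy / spacing) - r_px - 1)))
    r1 = min(h, int(math.ceil((cy / spacing) + r_px + 2)))
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1) * spacing - cx
    rows = np.arange(r0, r1) * spacing - cy
    d2 = rows[:, None] ** 2 + cols[None, :] ** 2
    mask = d2 <= radius * radius
    img[r0:r1, c0:c1][mask] = color


def _draw_annulus(img, cx, cy, r_in, r_out, color, spacing):
    h, w = img.shape[:2]
    rp = r_out / spacing
    c0 = max(0, int(math.floor(cx / spacing - rp - 1)))
    c1 = min(w, int(math.ceil(cx / spacing + rp + 2)))
    r0 = max(0, int(math.floor(cy / spacing - rp - 1)))
    r1 = min(h, int(math.ceil(cy / spacing + rp + 2)))
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1) * spacing - cx
    rows = np.arange(r0, r1) * spacing - cy
    d2 = rows[:, None] ** 2 + cols[None, :] ** 2
    mask = (d2 >= r_in * r_in) & (d2 <= r_out * r_out)
    img[r0:r1, c0:c1][mask] = color


def _section_perturbations(spec: PhantomSpec, rng) -> list:
    """Independent per-section world->section transforms; section 1 is the
    untransformed base.  Independent draws (no drift), so accumulated error
    growth under a biased registration is attributable to the method."""
    center = spec.ellipse_center
    out = [AffineTransform2D.identity()]
    for _ in range(spec.n_sections - 1):
        theta = math.radians(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
        t = rng.uniform(-spec.max_translation_um, spec.max_translation_um, size=2)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        if spec.affine_deviation > 0:
            dev = rng.uniform(-spec.affine_deviation, spec.affine_deviation, size=(2, 2))
            m = rot @ (np.eye(2) + dev)
            rigid = False
        else:
            m = rot
            rigid = True
        trans = t + center - m @ center
        out.append(AffineTransform2D(m, trans, is_rigid_constrained=rigid))
    return out


def _cap_radius(r: float, z: float, z0: float, z1: float) -> float:
    """Radius of the largest circle of a sphere (centre depth z, radius r)
    visible within the slab [z0, z1]; 0 if the sphere misses the slab."""
    if z0 <= z <= z1:
        return r
    gap = z0 - z if z < z0 else z - z1
    if gap >= r:
        return 0.0
    return math.sqrt(r * r - gap * gap)


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Generate a serial-section stack and its exact ground truth."""
    for v in spec.vessels:
        a, b = spec.ellipse_semiaxes
        cen = spec.ellipse_center
        depth = spec.n_sections * spec.section_thickness_um
        for z in (0.0, depth):
            p = v.center_at(z)
            rel = (p - cen) / np.array([a, b])
            if np.sum(rel * rel) > 1.0:
                raise ValueError("vessel centerline leaves the tissue footprint")

    rng = np.random.default_rng(spec.seed)
    sp = spec.pixel_spacing_um
    th = spec.section_thickness_um
    H = int(round(spec.extents_um[0] / sp))
    W = int(round(spec.extents_um[1] / sp))
    cen = spec.ellipse_center
    a, b = spec.ellipse_semiaxes
    depth = spec.n_sections * th

    # --- nuclei uniformly in the elliptical slab -----------------------
    n_nuclei = int(rng.poisson(spec.nucleus_density_per_mm2 * spec.tissue_area_mm2 * spec.n_sections))
    u = np.sqrt(rng.uniform(0, 1, n_nuclei))
    ang = rng.uniform(0, 2 * math.pi, n_nuclei)
    nx = cen[0] + a * u * np.cos(ang)
    ny = cen[1] + b * u * np.sin(ang)
    nz = rng.uniform(0, depth, n_nuclei)
    lo, hi = spec.nucleus_diameter_range_um
    nd = np.clip(
        rng.normal(spec.nucleus_diameter_mean_um, spec.nucleus_diameter_sd_um, n_nuclei), lo, hi
    )
    centers = np.column_stack([nx, ny, nz])

    # --- perturbations and textures ------------------------------------
    transforms = _section_perturbations(spec, rng)
    shared_tex = _smooth_field(rng, (H, W), spec.texture_shared_sigma_um / sp, spec.texture_shared_amp)

    # tissue mask on the pixel grid: a lobed ellipse.  The outward low-order
    # boundary lobes give the section outline the rotational asymmetry real
    # muscle cross-sections have, which the coarse intensity registration
    # needs to determine rotation; lobes only extend the base ellipse, so
    # everything sampled inside the ellipse stays within tissue.
    cols = np.arange(W) * sp
    rows = np.arange(H) * sp
    rel_x = (cols - cen[0]) / a
    rel_y = (rows - cen[1]) / b
    rel_r2 = rel_y[:, None] ** 2 + rel_x[None, :] ** 2
    phi = np.arctan2(np.broadcast_to(rel_y[:, None], (H, W)),
                     np.broadcast_to(rel_x[None, :], (H, W)))
    lobe_phases = rng.uniform(0, 2 * math.pi, size=2)
    a2, a3 = spec.boundary_lobe_amps
    r_max = (
        1.0
        + a2 * (1.0 + np.sin(2 * phi + lobe_phases[0])) / 2.0
        + a3 * (1.0 + np.sin(3 * phi + lobe_phases[1])) / 2.0
    )
    tissue = rel_r2 <= r_max * r_max

    # static world-frame canvas: tissue base plus pale interstitial blobs.
    # Blobs model fibre-boundary/interstitial space: pale 3-D columns shared
    # by all sections, providing the fine near-white structure the
    # window/levelled neighbourhood matching keys on.
    base_canvas = np.empty((H, W, 3), dtype=float)
    base_canvas[:] = COLOR_BACKGROUND
    for ch in range(3):
        base_canvas[:, :, ch][tissue] = COLOR_TISSUE[ch]
    r_lo, r_hi = spec.interstitial_radius_um
    mean_blob_area = math.pi * (r_lo * r_lo + r_lo * r_hi + r_hi * r_hi) / 3.0
    n_blobs = int(round(spec.interstitial_coverage * spec.tissue_area_mm2 * 1e6 / mean_blob_area))
    bu = np.sqrt(rng.uniform(0, 1, n_blobs))
    bang = rng.uniform(0, 2 * math.pi, n_blobs)
    bx = cen[0] + a * bu * np.cos(bang)
    by = cen[1] + b * bu * np.sin(bang)
    br = rng.uniform(r_lo, r_hi, n_blobs)
    for i in range(n_blobs):
        _draw_disk(base_canvas, bx[i], by[i], br[i], COLOR_INTERSTITIAL, sp)
    base_canvas[~tissue] = COLOR_BACKGROUND

    sections = []
    landmarks: dict = {}
    vessel_world: dict = {}
    vessel_rendered: dict = {}
    for k in range(1, spec.n_sections + 1):
        z0, z1 = (k - 1) * th, k * th
        img = base_canvas.copy()
        tex = shared_tex + _smooth_field(
            rng, (H, W), spec.texture_section_sigma_um / sp, spec.texture_section_amp
        )
        for ch in range(3):
            img[:, :, ch][tissue] += tex[tissue]
        # vessel wall annuli at the slab mid-depth
        zmid = (z0 + z1) / 2.0
        for vi, v in enumerate(spec.vessels):
            c = v.center_at(zmid)
            _draw_annulus(img, c[0], c[1], v.inner_radius_um, v.outer_radius_um, COLOR_VESSEL, sp)
            if vi == 0:
                vessel_world[k] = c
        # nuclei intersecting the slab
        ids, world_pos, areas = [], [], []
        ids_all, world_all = [], []
        near = np.where((nz > z0 - nd / 2.0) & (nz < z1 + nd / 2.0))[0]
        for i in near:
            rp = _cap_radius(nd[i] / 2.0, nz[i], z0, z1)
            if rp <= 0.4 * sp:
                continue
            _draw_disk(img, nx[i], ny[i], rp, COLOR_NUCLEUS, sp)
            ids_all.append(i)
            world_all.append((nx[i], ny[i]))
            area = math.pi * rp * rp
            if area >= DETECTABLE_AREA_UM2:
                ids.append(i)
                world_pos.append((nx[i], ny[i]))
                areas.append(area)
        np.clip(img, 0, 255, out=img)
        base = SectionImage(
            np.asarray(round_half_up(img), dtype=np.uint8), spacing=sp, index=k, thickness=th
        )
        # apply the inverse perturbation: rendered(x) = world(S_k^{-1}(x))
        s_k = transforms[k - 1]
        warped = base if s_k.almost_equals(AffineTransform2D.identity()) else resample_image(base, s_k)
        noisy = np.asarray(warped.pixels, dtype=float) + rng.normal(0, spec.noise_sd, (H, W, 3))
        sections.append(
            SectionImage(
                np.asarray(round_half_up(np.clip(noisy, 0, 255)), dtype=np.uint8),
                spacing=sp, index=k, thickness=th,
            )
        )
        wp = np.array(world_pos).reshape(-1, 2)
        wa = np.array(world_all).reshape(-1, 2)
        landmarks[k] = {
            "ids": np.array(ids, dtype=int),
            "world": wp,
            "rendered": s_k.apply(wp) if len(wp) else wp,
            "area": np.array(areas),
            "ids_all": np.array(ids_all, dtype=int),
            "rendered_all": s_k.apply(wa) if len(wa) else wa,
        }
        vessel_rendered[k] = s_k.apply(vessel_world[k])

    # --- homologous pairs across each cutting plane ---------------------
    pairs = []
    split: dict = {}
    for k in range(1, spec.n_sections):
        zb = k * th
        ids_k = set(landmarks[k]["ids"].tolist())
        ids_k1 = set(landmarks[k + 1]["ids"].tolist())
        for i in ids_k & ids_k1:
            if abs(nz[i] - zb) >= nd[i] / 2.0:
                continue  # visible on both but not bisected by this plane
            p_world = centers[i, :2]
            pairs.append(
                {
                    "section": k,
                    "nucleus_id": int(i),
                    "p_I": transforms[k - 1].apply(p_world),
                    "p_J": transforms[k].apply(p_world),
                }
            )
            split[int(i)] = "reference" if rng.uniform() < spec.reference_fraction else "registration"

    pairwise = [
        compose(transforms[k], transforms[k + 1].invert())
        for k in range(spec.n_sections - 1)
    ]
    gt = PhantomGroundTruth(
        spec=spec,
        section_transforms=transforms,
        chain=TransformChain(pairwise),
        nucleus_centers=centers,
        nucleus_diameters=nd,
        landmarks=landmarks,
        pairs=pairs,
        split=split,
        vessel_centroids_world=vessel_world,
        vessel_centroids_rendered=vessel_rendered,
    )
    return sections, gt


# ----------------------------------------------------------------------
# ground-truth accessors
# ----------------------------------------------------------------------

def ground_truth_pairs(gt: PhantomGroundTruth, split: str = "reference"):
    """Homologous centroid pairs per adjacent section pair, in the rendered
    section frames, restricted to the requested split.

    Returns a dict mapping the fixed-section index k to (P_I, P_J) arrays:
    positions on section k and on section k+1 of the same bisected nuclei.
    The registration and reference splits are disjoint.
    """
    if split not in ("registration", "reference"):
        raise ValueError(f"unknown split {split!r}")
    out: dict = {}
    for k in range(1, gt.spec.n_sections):
        sel = [p for p in gt.pairs if p["section"] == k and gt.split[p["nucleus_id"]] == split]
        out[k] = (
            np.array([p["p_I"] for p in sel]).reshape(-1, 2),
            np.array([p["p_J"] for p in sel]).reshape(-1, 2),
        )
    return out


def detect_vessel_centroids(stack: Sequence[SectionImage]) -> dict:
    """Locate the DAB-brown vessel-wall centroid on each section (μm).

    Brown pixels are detected as strongly red-over-blue with a sub-threshold
    green channel; sections with no vessel pixels map to None.
    """
    out = {}
    for s in stack:
        px = s.pixels.astype(int)
        mask = (px[:, :, 0] - px[:, :, 2] > 50) & (px[:, :, 1] < 200)
        if mask.sum() < 20:
            out[s.index] = None
            continue
        rr, cc = np.nonzero(mask)
        out[s.index] = np.array([cc.mean() * s.spacing, rr.mean() * s.spacing])
    return out


def vessel_axis_angle(
    centroids, chain: TransformChain, thickness: float
) -> float:
    """Angle (degrees) between the reconstructed vessel axis and the section
    normal.

    ``centroids`` maps 1-based section indices to in-plane vessel centroids
    (μm, section frames), or is a :class:`PhantomGroundTruth` (its rendered
    vessel centroids are used).  Each centroid is mapped into the section-1
    frame through the chain, given z = (section − 1) × thickness, and a 3-D
    line is fit by total least squares; the return value is the angle of its
    direction to the z-axis.
    """
    if isinstance(centroids, PhantomGroundTruth):
        centroids = centroids.vessel_centroids_rendered
    pts = []
    for k in sorted(centroids):
        c = centroids[k]
        if c is None:
            continue
        xy = chain.map_to_reference(k, np.asarray(c, dtype=float))
        pts.append([xy[0], xy[1], (k - 1) * thickness])
    pts = np.array(pts)
    if len(pts) < 3:
        raise ValueError("vessel must be visible on at least 3 sections")
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    cos_z = abs(direction[2]) / np.linalg.norm(direction)
    return float(np.degrees(np.arccos(np.clip(cos_z, -1.0, 1.0))))
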