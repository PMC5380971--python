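"""Synthetic microscopy fields and time-lapse series with ground truth.

The generator emulates the statistical structure the analysis assumes:
cells with one nucleus each; lipid droplets rendered as discs with a
right-skewed (log-normal) area distribution dominated by areas below
0.5 μm²; a controllable fraction of droplets placed in clusters with
planted boundary gaps at or below the 2-pixel cluster criterion while
distinct entities stay well separated; diffraction-limited marker foci
at droplet surfaces and droplet–droplet contacts (3D Gaussians in a
z-stack); Poisson–Gaussian noise at a requested peak-signal-to-noise
ratio; and two-state Markov association/dissociation kinetics for
time-lapse series.  Every random draw comes from one explicit
generator, so the same spec and seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import DEFAULT_PIXEL_SIZE_UM, FieldImage

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "PlantedFocus",
    "TimelapseEvent",
    "PlacementError",
    "generate_field",
    "generate_timelapse",
    "write_ground_truth",
]


class PlacementError(RuntimeError):
    """Raised when requested objects cannot be placed without violating a
    geometric constraint within the retry budget."""


@dataclass
class FieldSpec:
    """Parameters of one synthetic field.

    Defaults emulate oleic-acid-loaded cultured cells imaged at
    0.133 μm/px: on the order of a hundred droplets per cell, ~90% of
    droplet areas below 0.5 μm² (log-normal), roughly a third of the
    droplets sitting in clusters whose planted boundary gaps are at or
    below 2 px while distinct entities keep gaps of at least 6 px.
    """

    width_px: int = 768
    height_px: int = 768
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 4
    nucleus_diameter_px_range: tuple[float, float] = (110.0, 160.0)
    cell_radius_factor: float = 2.2  # cell radius as multiple of nucleus radius
    ld_count_per_cell: float = 100.0  # Poisson mean
    ld_area_um2_median: float = 0.2
    ld_area_um2_sigma: float = 0.7  # log-normal shape
    ld_min_radius_px: float = 1.3
    cluster_fraction: float = 0.3
    cluster_gap_px_range: tuple[float, float] = (0.8, 1.8)
    cluster_size_probs: tuple[tuple[int, float], ...] = (
        (2, 0.55),
        (3, 0.25),
        (4, 0.12),
        (5, 0.06),
        (6, 0.02),
    )
    min_separation_px: float = 6.0
    snr: float = 8.0
    psf_sigma_px: float = 0.8
    foreground_intensity: float = 1000.0
    background_intensity: float = 100.0
    # marker z-stack (off unless marker_patches_per_ld > 0)
    marker_patches_per_ld: int = 0
    marker_patches_per_ineligible_ld: int = 0
    contact_patches_per_pair: int = 1
    n_z: int = 9
    z_step_um: float = 0.25
    focus_sigma_px: float = 1.5
    focus_sigma_z_planes: float = 1.0
    # time-lapse geometry
    n_pairs: int = 60
    dissociated_gap_px: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_cells) <= 0:
            raise ValueError("field dimensions and n_cells must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        lo, hi = self.nucleus_diameter_px_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus_diameter_px_range must satisfy 0 < lo <= hi")
        g0, g1 = self.cluster_gap_px_range
        if not 0 < g0 <= g1:
            raise ValueError("cluster_gap_px_range must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")
        if self.ld_count_per_cell <= 0 or self.ld_area_um2_median <= 0:
            raise ValueError("droplet count and area parameters must be positive")


@dataclass
class PlantedFocus:
    position: tuple[int, float, float]  # (z, row, col)
    intensity: float
    ld_ids: tuple[int, ...]
    at_contact_site: bool
    host_eligible: bool = True


@dataclass
class TimelapseEvent:
    frame: int
    time_s: float
    pair_id: int
    kind: str  # "dissociate" | "associate" | "fuse"
    marker_positive: bool | None = None
    marker_onset: str | None = None  # "before" | "during"
    site: tuple[float, float] | None = None


@dataclass
class GroundTruth:
    """Complete planted truth for one field or time-lapse series."""

    nucleus_labels: np.ndarray | None = None
    cell_labels: np.ndarray | None = None
    ld_labels: np.ndarray | None = None
    ld_areas_um2: dict[int, float] = field(default_factory=dict)
    ld_centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    ld_cell: dict[int, int] = field(default_factory=dict)
    planted_clusters: list[frozenset[int]] = field(default_factory=list)
    planted_foci: list[PlantedFocus] = field(default_factory=list)
    # time-lapse only
    event_log: list[TimelapseEvent] = field(default_factory=list)
    pair_states: np.ndarray | None = None  # (n_pairs, n_frames) of "A"/"D"/"F"
    pair_centers: dict[int, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _disc_pixels(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel centres within ``radius`` of ``center`` (clipped to image)."""
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[m], cc[m]


def _coords_gap(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> float:
    tree = cKDTree(np.column_stack(b))
    d, _ = tree.query(np.column_stack(a), k=1)
    return float(d.min())


def _render(
    shape: tuple[int, int],
    coords: Sequence[tuple[np.ndarray, np.ndarray]],
    amplitudes: Sequence[float],
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    for (rr, cc), amp in zip(coords, amplitudes):
        img[rr, cc] = amp
    return img


def _finish_channel(
    clean: np.ndarray, spec: FieldSpec, rng: np.random.Generator
) -> np.ndarray:
    """Blur, add background and Poisson–Gaussian noise, quantize to uint16.

    The noise model targets a background standard deviation of
    ``foreground_intensity / snr``: a Poisson term at the background
    level plus Gaussian read noise making up the remaining variance.
    ``snr = inf`` renders exactly (blur only, no noise).
    """
    if spec.psf_sigma_px > 0:
        clean = ndimage.gaussian_filter(clean, spec.psf_sigma_px)
    return _apply_noise(clean, spec, rng)


def _apply_noise(
    clean: np.ndarray, spec: FieldSpec, rng: np.random.Generator
) -> np.ndarray:
    """Poisson–Gaussian noise on a background offset, quantized to uint16."""
    if np.isinf(spec.snr):
        out = clean + spec.background_intensity
    else:
        sigma = spec.foreground_intensity / spec.snr
        # raise the offset when noise is strong so the Gaussian tail is
        # not clipped at zero (which would distort the target s.d.)
        offset = max(spec.background_intensity, 4.0 * sigma)
        read_var = max(sigma**2 - offset, 0.0)
        out = rng.poisson(clean + offset).astype(float)
        if read_var > 0:
            out = out + rng.normal(0.0, np.sqrt(read_var), size=clean.shape)
        else:  # Poisson alone already exceeds the target; rescale around offset
            out = offset + (out - offset) * (sigma / np.sqrt(offset))
    return np.clip(np.round(out), 0, 2**16 - 1).astype(np.uint16)


# ---------------------------------------------------------------------------
# still field
# ---------------------------------------------------------------------------

def generate_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one multi-channel field (nuclei, cytoplasm, LD, optional
    marker z-stack) with complete planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)

    cell_centers, nucleus_radii, cell_radii = _place_cells(spec, rng)
    n_labels = np.zeros(shape, dtype=np.int32)
    c_labels = np.zeros(shape, dtype=np.int32)
    for i, (ctr, rn, rc) in enumerate(zip(cell_centers, nucleus_radii, cell_radii), start=1):
        rr, cc = _disc_pixels(ctr, rc, shape)
        c_labels[rr, cc] = i
        rr, cc = _disc_pixels(ctr, rn, shape)
        n_labels[rr, cc] = i

    gt = GroundTruth(nucleus_labels=n_labels, cell_labels=c_labels)
    ld_coords = _place_droplets(spec, rng, cell_centers, nucleus_radii, cell_radii, gt, shape)

    ld_labels = np.zeros(shape, dtype=np.int32)
    amps = {}
    for lid, (rr, cc) in ld_coords.items():
        ld_labels[rr, cc] = lid
        amps[lid] = spec.foreground_intensity * rng.uniform(0.8, 1.2)
    gt.ld_labels = ld_labels

    nuclei_img = _render(shape, [_mask_coords(n_labels, i) for i in range(1, spec.n_cells + 1)],
                         [spec.foreground_intensity] * spec.n_cells)
    cyto_img = _render(shape, [_mask_coords(c_labels, i) for i in range(1, spec.n_cells + 1)],
                       [spec.foreground_intensity] * spec.n_cells)
    ld_img = _render(shape, list(ld_coords.values()), [amps[l] for l in ld_coords])

    channels = {
        "nuclei": _finish_channel(nuclei_img, spec, rng),
        "cytoplasm": _finish_channel(cyto_img, spec, rng),
        "ld": _finish_channel(ld_img, spec, rng),
    }
    if spec.marker_patches_per_ld > 0 or spec.marker_patches_per_ineligible_ld > 0:
        channels["marker"] = _render_marker_stack(spec, rng, gt, shape)

    image = FieldImage(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um if "marker" in channels else None,
    )
    return image, gt


def _mask_coords(labels: np.ndarray, lab: int) -> tuple[np.ndarray, np.ndarray]:
    return np.nonzero(labels == lab)


def _place_cells(
    spec: FieldSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Jittered-grid cell placement; cells never touch the border or
    each other."""
    max_rc = spec.cell_radius_factor * spec.nucleus_diameter_px_range[1] / 2
    n_cols = int(np.ceil(np.sqrt(spec.n_cells * spec.width_px / spec.height_px)))
    n_rows = int(np.ceil(spec.n_cells / n_cols))
    pitch_r = spec.height_px / n_rows
    pitch_c = spec.width_px / n_cols
    if min(pitch_r, pitch_c) < 2 * max_rc + 4:
        raise PlacementError(
            f"cannot fit {spec.n_cells} cells of radius up to {max_rc:.0f} px "
            f"into a {spec.height_px}x{spec.width_px} field without contact"
        )
    centers, n_radii, c_radii = [], [], []
    slots = [(i, j) for i in range(n_rows) for j in range(n_cols)][: spec.n_cells]
    for i, j in slots:
        rn = rng.uniform(*spec.nucleus_diameter_px_range) / 2
        rc = spec.cell_radius_factor * rn
        jitter = (min(pitch_r, pitch_c) / 2 - rc - 2) * 0.5
        ctr = (
            (i + 0.5) * pitch_r + rng.uniform(-jitter, jitter),
            (j + 0.5) * pitch_c + rng.uniform(-jitter, jitter),
        )
        centers.append(ctr)
        n_radii.append(rn)
        c_radii.append(rc)
    return centers, n_radii, c_radii


def _sample_radius_px(spec: FieldSpec, rng: np.random.Generator) -> float:
    area = rng.lognormal(np.log(spec.ld_area_um2_median), spec.ld_area_um2_sigma)
    r = np.sqrt(area / np.pi) / spec.pixel_size_um
    return max(r, spec.ld_min_radius_px)


def _cluster_sizes(spec: FieldSpec, n_clustered: int, rng: np.random.Generator) -> list[int]:
    sizes, probs = zip(*spec.cluster_size_probs)
    out: list[int] = []
    left = n_clustered
    while left >= 2:
        k = int(rng.choice(sizes, p=np.asarray(probs) / np.sum(probs)))
        k = min(k, left)
        if k < 2:
            break
        out.append(k)
        left -= k
    return out


def _place_droplets(
    spec: FieldSpec,
    rng: np.random.Generator,
    cell_centers: list[tuple[float, float]],
    nucleus_radii: list[float],
    cell_radii: list[float],
    gt: GroundTruth,
    shape: tuple[int, int],
    retries: int = 300,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Place singleton droplets and cluster chains inside each cell.

    Planted gaps inside a cluster are verified on the rasterized masks
    to be within (0, 2] px; distinct entities keep continuous gaps of at
    least ``min_separation_px``, so the planted cluster partition equals
    the transitive closure of the 2-px gap relation by construction.
    """
    coords: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    placed: list[tuple[float, float, float]] = []  # (r, c, radius) all cells
    next_id = 1

    for cell_id, (ctr, rn, rc) in enumerate(
        zip(cell_centers, nucleus_radii, cell_radii), start=1
    ):
        n_ld = max(int(rng.poisson(spec.ld_count_per_cell)), 1)
        n_clustered = int(round(spec.cluster_fraction * n_ld))
        sizes = _cluster_sizes(spec, n_clustered, rng)
        n_singletons = n_ld - sum(sizes)
        entities = [("cluster", k) for k in sizes] + [("singleton", 1)] * n_singletons
        rng.shuffle(entities)

        def sample_center(radius: float) -> tuple[float, float]:
            for _ in range(retries):
                ang = rng.uniform(0, 2 * np.pi)
                lo = rn + radius + 1.5
                hi = rc - radius - 2.0
                if hi <= lo:
                    continue
                rho = np.sqrt(rng.uniform(lo**2, hi**2))
                p = (ctr[0] + rho * np.sin(ang), ctr[1] + rho * np.cos(ang))
                if _clear(p, radius, placed, spec.min_separation_px):
                    return p
            raise PlacementError(
                f"cell {cell_id}: could not place droplet of radius {radius:.1f} px "
                f"with min separation {spec.min_separation_px} px"
            )

        for kind, k in entities:
            members: list[tuple[float, float, float]] = []
            radius = _sample_radius_px(spec, rng)
            p = sample_center(radius)
            members.append((p[0], p[1], radius))
            ok = True
            for _ in range(k - 1):
                nxt = _chain_next(spec, rng, members, placed, ctr, rn, rc, shape, retries)
                if nxt is None:
                    ok = False
                    break
                members.append(nxt)
            if not ok:  # cluster placement failed; fall back to the anchor alone
                members = members[:1]
            ids = []
            for r, c, rad in members:
                rr, cc = _disc_pixels((r, c), rad, shape)
                coords[next_id] = (rr, cc)
                gt.ld_areas_um2[next_id] = rr.size * spec.pixel_size_um**2
                gt.ld_centroids[next_id] = (float(rr.mean()), float(cc.mean()))
                gt.ld_cell[next_id] = cell_id
                placed.append((r, c, rad))
                ids.append(next_id)
                next_id += 1
            if len(ids) >= 2:
                gt.planted_clusters.append(frozenset(ids))
    return coords


def _clear(
    p: tuple[float, float],
    radius: float,
    placed: list[tuple[float, float, float]],
    min_sep: float,
) -> bool:
    for r, c, rad in placed:
        if np.hypot(p[0] - r, p[1] - c) < radius + rad + min_sep:
            return False
    return True


def _chain_next(
    spec: FieldSpec,
    rng: np.random.Generator,
    members: list[tuple[float, float, float]],
    placed: list[tuple[float, float, float]],
    cell_ctr: tuple[float, float],
    rn: float,
    rc: float,
    shape: tuple[int, int],
    retries: int,
) -> tuple[float, float, float] | None:
    """Append one droplet to a cluster chain with a rasterized boundary
    gap in (0, 2] px to the previous member."""
    pr, pc, prad = members[-1]
    prev_px = _disc_pixels((pr, pc), prad, shape)
    radius = _sample_radius_px(spec, rng)
    for _ in range(retries):
        gap = rng.uniform(*spec.cluster_gap_px_range)
        ang = rng.uniform(0, 2 * np.pi)
        d = prad + radius + gap
        p = (pr + d * np.sin(ang), pc + d * np.cos(ang))
        if np.hypot(p[0] - cell_ctr[0], p[1] - cell_ctr[1]) > rc - radius - 2.0:
            continue
        if np.hypot(p[0] - cell_ctr[0], p[1] - cell_ctr[1]) < rn + radius + 1.5:
            continue
        if not _clear(p, radius, placed, spec.min_separation_px):
            continue
        # same-cluster members other than the previous one: disjoint is enough
        if any(
            np.hypot(p[0] - r, p[1] - c) < radius + rad + 0.8
            for r, c, rad in members[:-1]
        ):
            continue
        # verify the rasterized gap respects the planted criterion; the
        # acceptance window tracks the requested gap range but never
        # exceeds the 2-px cluster rule
        px = _disc_pixels(p, radius, shape)
        if px[0].size == 0:
            continue
        g = _coords_gap(px, prev_px)
        if 0.5 < g <= min(2.0, spec.cluster_gap_px_range[1] + 0.3):
            return (p[0], p[1], radius)
    return None


# ---------------------------------------------------------------------------
# marker z-stack
# ---------------------------------------------------------------------------

def _render_marker_stack(
    spec: FieldSpec,
    rng: np.random.Generator,
    gt: GroundTruth,
    shape: tuple[int, int],
    assign_radius_px: float | None = None,
    retries: int = 200,
) -> np.ndarray:
    """Plant diffraction-limited foci at eligible droplet surfaces and at
    contacts between eligible droplets, render them as 3D Gaussians."""
    if assign_radius_px is None:
        assign_radius_px = 0.3 / spec.pixel_size_um
    min_diam_um = 1.0
    eligible = {
        lid
        for lid, a in gt.ld_areas_um2.items()
        if 2 * np.sqrt(a / np.pi) >= min_diam_um
    }
    ld_px = {lid: np.column_stack(np.nonzero(gt.ld_labels == lid)) for lid in gt.ld_areas_um2}
    trees = {lid: cKDTree(px) for lid, px in ld_px.items()}

    def min_dist_to_others(p: tuple[float, float], skip: set[int]) -> float:
        best = np.inf
        for lid, tree in trees.items():
            if lid in skip:
                continue
            d, _ = tree.query([p], k=1)
            best = min(best, float(d[0]))
        return best

    foci: list[PlantedFocus] = []

    def far_from_planted(p: tuple[float, float], min_lat: float = 3.2) -> bool:
        return all(
            np.hypot(p[0] - f.position[1], p[1] - f.position[2]) >= min_lat for f in foci
        )

    def plant_surface(lid: int, count: int, host_eligible: bool) -> None:
        ctr = gt.ld_centroids[lid]
        r_eff = np.sqrt(gt.ld_areas_um2[lid] / np.pi) / spec.pixel_size_um
        for _ in range(count):
            for _ in range(retries):
                ang = rng.uniform(0, 2 * np.pi)
                p = (ctr[0] + r_eff * np.sin(ang), ctr[1] + r_eff * np.cos(ang))
                if not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]):
                    continue
                if min_dist_to_others(p, {lid}) <= assign_radius_px + 1.0:
                    continue
                if not far_from_planted(p):
                    continue
                z = int(rng.integers(2, spec.n_z - 2))
                foci.append(
                    PlantedFocus(
                        position=(z, p[0], p[1]),
                        intensity=spec.foreground_intensity * rng.uniform(0.9, 1.1),
                        ld_ids=(lid,) if host_eligible else (),
                        at_contact_site=False,
                        host_eligible=host_eligible,
                    )
                )
                break

    for lid in sorted(eligible):
        plant_surface(lid, spec.marker_patches_per_ld, True)
    if spec.marker_patches_per_ineligible_ld > 0:
        for lid in sorted(set(gt.ld_areas_um2) - eligible):
            # only isolated hosts, so the focus cannot leak onto an eligible LD
            ctr = gt.ld_centroids[lid]
            if min_dist_to_others(ctr, {lid}) > assign_radius_px + 4.0:
                plant_surface(lid, spec.marker_patches_per_ineligible_ld, False)

    # contact foci between eligible droplets whose rasterized gap <= 2 px
    elig = sorted(eligible)
    for i, a in enumerate(elig):
        for b in elig[i + 1 :]:
            ta = ld_px[a]
            d, idx = trees[b].query(ta, k=1)
            j = int(np.argmin(d))
            if d[j] > 2.0:
                continue
            pa = ta[j]
            pb = ld_px[b][idx[j]]
            mid = ((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)
            for _ in range(spec.contact_patches_per_pair):
                if not far_from_planted(mid):
                    break
                z = int(rng.integers(2, spec.n_z - 2))
                foci.append(
                    PlantedFocus(
                        position=(z, mid[0], mid[1]),
                        intensity=spec.foreground_intensity * rng.uniform(0.9, 1.1),
                        ld_ids=(a, b),
                        at_contact_site=True,
                    )
                )

    gt.planted_foci = foci
    stack = np.zeros((spec.n_z,) + shape, dtype=float)
    for f in foci:
        _add_gaussian_3d(stack, f.position, f.intensity, spec.focus_sigma_px, spec.focus_sigma_z_planes)
    # per-plane background and noise (no extra lateral blur: sigma is the PSF)
    out = np.empty_like(stack, dtype=np.uint16)
    for z in range(spec.n_z):
        out[z] = _apply_noise(stack[z], spec, rng)
    return out


def _add_gaussian_3d(
    stack: np.ndarray,
    position: tuple[float, float, float],
    amplitude: float,
    sigma_lat: float,
    sigma_z: float,
) -> None:
    z0, r0, c0 = position
    zz = np.arange(stack.shape[0])
    ext = int(np.ceil(4 * sigma_lat))
    ra = max(int(np.floor(r0)) - ext, 0)
    rb = min(int(np.ceil(r0)) + ext + 1, stack.shape[1])
    ca = max(int(np.floor(c0)) - ext, 0)
    cb = min(int(np.ceil(c0)) + ext + 1, stack.shape[2])
    rr, cc = np.mgrid[ra:rb, ca:cb]
    lat = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_lat**2)))
    ax = np.exp(-((zz - z0) ** 2) / (2 * sigma_z**2))
    stack[:, ra:rb, ca:cb] += amplitude * ax[:, None, None] * lat[None]


# ---------------------------------------------------------------------------
# time-lapse
# ---------------------------------------------------------------------------

def generate_timelapse(
    spec: FieldSpec,
    duration_s: float = 300.0,
    frame_interval_s: float = 2.0,
    k_dissoc: float = 0.005,
    k_assoc: float = 0.005,
    marker_positive_fraction: float = 0.6,
    seed: int | None = None,
    k_fuse: float = 0.0,
    marker_before_fraction: float = 0.7,
    marker_pre_frames: int = 3,
) -> tuple[FieldImage, GroundTruth]:
    """Render a time-lapse of droplet pairs with two-state Markov
    association kinetics sampled at the frame interval.

    Pairs start associated (planted boundary gap <= 2 px) and toggle to
    a dissociated geometry (gap ``spec.dissociated_gap_px``) with rates
    ``k_dissoc`` / ``k_assoc``; an optional fusion rate replaces an
    associated pair by one droplet of summed area.  Each frame-visible
    dissociation is marker positive with ``marker_positive_fraction``;
    positive events carry a marker focus at the pair midpoint starting
    ``marker_pre_frames`` before the separation ("before" onsets, with
    probability ``marker_before_fraction``) or at the separation frame
    ("during"), lasting until the pair re-associates.
    """
    if frame_interval_s <= 0 or duration_s < frame_interval_s:
        raise ValueError("need duration_s >= frame_interval_s > 0")
    if min(k_dissoc, k_assoc, k_fuse) < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.height_px, spec.width_px)
    n_frames = int(np.floor(duration_s / frame_interval_s)) + 1
    times = np.arange(n_frames) * frame_interval_s

    pairs = _place_pairs(spec, rng, shape)
    n_pairs = len(pairs)
    states = np.full((n_pairs, n_frames), "A", dtype="U1")
    gt = GroundTruth()
    events: list[TimelapseEvent] = []

    for pid, geom in enumerate(pairs, start=1):
        gt.pair_centers[pid] = geom["center"]
        st = _simulate_pair_states(
            rng, times, k_dissoc, k_assoc, k_fuse
        )
        states[pid - 1] = st
        prev = "A"
        for f in range(1, n_frames):
            cur = st[f]
            if cur == prev:
                continue
            kind = {"D": "dissociate", "A": "associate", "F": "fuse"}[cur]
            ev = TimelapseEvent(
                frame=f, time_s=float(times[f]), pair_id=pid, kind=kind,
                site=geom["center"],
            )
            if kind == "dissociate":
                ev.marker_positive = bool(rng.uniform() < marker_positive_fraction)
                if ev.marker_positive:
                    ev.marker_onset = (
                        "before" if rng.uniform() < marker_before_fraction else "during"
                    )
            events.append(ev)
            prev = cur

    gt.event_log = events
    gt.pair_states = states

    ld_frames = np.empty((n_frames,) + shape, dtype=np.uint16)
    want_marker = any(e.kind == "dissociate" for e in events)
    marker_frames = np.empty((n_frames,) + shape, dtype=np.uint16) if want_marker else None

    marker_spans = _marker_spans(events, states, marker_pre_frames, n_frames)
    for f in range(n_frames):
        clean = np.zeros(shape, dtype=float)
        for pid, geom in enumerate(pairs, start=1):
            _draw_pair(clean, geom, states[pid - 1, f])
        ld_frames[f] = _finish_channel(clean, spec, rng)
        if marker_frames is not None:
            mclean = np.zeros(shape, dtype=float)
            for pid, lo, hi in marker_spans:
                if lo <= f <= hi:
                    ctr = pairs[pid - 1]["center"]
                    _add_gaussian_2d(mclean, ctr, spec.foreground_intensity, spec.focus_sigma_px)
            marker_frames[f] = _finish_channel(mclean, spec, rng)

    channels = {"ld": ld_frames}
    if marker_frames is not None:
        channels["marker"] = marker_frames
    image = FieldImage(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        frame_interval_s=frame_interval_s,
    )
    return image, gt


def _simulate_pair_states(
    rng: np.random.Generator,
    times: np.ndarray,
    k_dissoc: float,
    k_assoc: float,
    k_fuse: float,
) -> np.ndarray:
    """Exact continuous-time simulation sampled at the frame times.

    States: A (associated), D (dissociated), F (fused, absorbing)."""
    jumps: list[tuple[float, str]] = []
    t, state = 0.0, "A"
    horizon = float(times[-1])
    while t <= horizon:
        if state == "A":
            t_d = t + rng.exponential(1.0 / k_dissoc) if k_dissoc > 0 else np.inf
            t_f = t + rng.exponential(1.0 / k_fuse) if k_fuse > 0 else np.inf
            if min(t_d, t_f) > horizon:
                break
            if t_d <= t_f:
                t, state = t_d, "D"
            else:
                t, state = t_f, "F"
            jumps.append((t, state))
            if state == "F":
                break
        else:  # dissociated
            if k_assoc <= 0:
                break
            t = t + rng.exponential(1.0 / k_assoc)
            if t > horizon:
                break
            state = "A"
            jumps.append((t, state))
    out = np.full(times.shape, "A", dtype="U1")
    cur = "A"
    ji = 0
    for i, tt in enumerate(times):
        while ji < len(jumps) and jumps[ji][0] <= tt:
            cur = jumps[ji][1]
            ji += 1
        out[i] = cur
    return out


def _place_pairs(
    spec: FieldSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> list[dict]:
    """Static pair geometries on a jittered grid, with the associated
    configuration verified to rasterize to a boundary gap <= 2 px."""
    margin = spec.dissociated_gap_px + 12.0
    n_cols = int(np.ceil(np.sqrt(spec.n_pairs * spec.width_px / spec.height_px)))
    n_rows = int(np.ceil(spec.n_pairs / n_cols))
    pitch_r = spec.height_px / n_rows
    pitch_c = spec.width_px / n_cols
    if min(pitch_r, pitch_c) < margin + 8:
        raise PlacementError(
            f"cannot place {spec.n_pairs} pairs in a "
            f"{spec.height_px}x{spec.width_px} field without interference"
        )
    pairs: list[dict] = []
    slots = [(i, j) for i in range(n_rows) for j in range(n_cols)][: spec.n_pairs]
    for i, j in slots:
        # radii clipped to a band the detector resolves at the planted
        # gaps; the pair toggles geometry, not size, across the movie
        r1 = np.clip(_sample_radius_px(spec, rng), 2.0, 3.2)
        r2 = np.clip(_sample_radius_px(spec, rng), 2.0, 3.2)
        center = (
            (i + 0.5) * pitch_r + rng.uniform(-2, 2),
            (j + 0.5) * pitch_c + rng.uniform(-2, 2),
        )
        # associated gaps well inside the 2-px criterion, so measured
        # gaps of detected masks stay below threshold despite noise
        geom = None
        for _ in range(500):  # resample geometry until the
            ang = rng.uniform(0, 2 * np.pi)
            u = (np.sin(ang), np.cos(ang))
            gap = rng.uniform(1.0, 1.4)  # rasterized gap lands in (0.9, 1.45]
            ctr = (center[0] + rng.uniform(-0.5, 0.5), center[1] + rng.uniform(-0.5, 0.5))
            d = r1 + r2 + gap
            pa = (ctr[0] - u[0] * d / 2, ctr[1] - u[1] * d / 2)
            pb = (ctr[0] + u[0] * d / 2, ctr[1] + u[1] * d / 2)
            ma = _disc_pixels(pa, r1, shape)
            mb = _disc_pixels(pb, r2, shape)
            if ma[0].size and mb[0].size:
                g = _coords_gap(ma, mb)
                if 0.9 < g <= 1.45:
                    center = ctr
                    geom = {
                        "center": center, "u": u, "r1": r1, "r2": r2,
                        "assoc": (ma, mb),
                    }
                    break
        if geom is None:
            raise PlacementError(
                "could not rasterize an associated pair with a boundary gap <= 1.5 px"
            )
        d = r1 + r2 + spec.dissociated_gap_px
        pa = (center[0] - u[0] * d / 2, center[1] - u[1] * d / 2)
        pb = (center[0] + u[0] * d / 2, center[1] + u[1] * d / 2)
        geom["dissoc"] = (_disc_pixels(pa, r1, shape), _disc_pixels(pb, r2, shape))
        geom["fused"] = _disc_pixels(center, float(np.hypot(r1, r2)), shape)
        geom["amp"] = spec.foreground_intensity * rng.uniform(0.9, 1.1)
        pairs.append(geom)
    return pairs


def _draw_pair(img: np.ndarray, geom: dict, state: str) -> None:
    amp = geom["amp"]
    if state == "F":
        rr, cc = geom["fused"]
        img[rr, cc] = amp
    else:
        key = "assoc" if state == "A" else "dissoc"
        for rr, cc in geom[key]:
            img[rr, cc] = amp


def _marker_spans(
    events: list[TimelapseEvent],
    states: np.ndarray,
    marker_pre_frames: int,
    n_frames: int,
) -> list[tuple[int, int, int]]:
    """(pair_id, first_frame, last_frame) spans of rendered marker foci."""
    spans = []
    for ev in events:
        if ev.kind != "dissociate" or not ev.marker_positive:
            continue
        lo = ev.frame - marker_pre_frames if ev.marker_onset == "before" else ev.frame
        lo = max(lo, 0)
        hi = ev.frame
        row = states[ev.pair_id - 1]
        while hi + 1 < n_frames and row[hi + 1] == "D":
            hi += 1
        spans.append((ev.pair_id, lo, hi))
    return spans


def _add_gaussian_2d(
    img: np.ndarray, center: tuple[float, float], amplitude: float, sigma: float
) -> None:
    r0, c0 = center
    ext = int(np.ceil(4 * sigma))
    ra = max(int(np.floor(r0)) - ext, 0)
    rb = min(int(np.ceil(r0)) + ext + 1, img.shape[0])
    ca = max(int(np.floor(c0)) - ext, 0)
    cb = min(int(np.ceil(c0)) + ext + 1, img.shape[1])
    rr, cc = np.mgrid[ra:rb, ca:cb]
    img[ra:rb, ca:cb] += amplitude * np.exp(
        -(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_detection(
    droplets,
    gt: GroundTruth,
    max_match_dist_px: float = 3.0,
) -> dict:
    """Score detected droplets against the planted ground truth.

    Greedy one-to-one matching of planted centroids to the nearest free
    detection within ``max_match_dist_px``.  Returns precision, recall,
    F1 and the per-droplet relative area errors of matched pairs.
    """
    dets = list(droplets)
    if not dets or not gt.ld_centroids:
        return {
            "tp": 0, "fp": len(dets), "fn": len(gt.ld_centroids),
            "precision": 0.0, "recall": 0.0, "f1": 0.0,
            "area_errors": np.array([]), "matches": {},
        }
    cents = np.array([d.centroid for d in dets])
    tree = cKDTree(cents)
    used: set[int] = set()
    matches: dict[int, int] = {}
    area_errors = []
    k = min(4, len(dets))
    for gid, p in gt.ld_centroids.items():
        dd, jj = tree.query(p, k=k)
        dd = np.atleast_1d(dd)
        jj = np.atleast_1d(jj)
        for d, j in zip(dd, jj):
            if d <= max_match_dist_px and int(j) not in used:
                used.add(int(j))
                matches[gid] = int(j)
                truth = gt.ld_areas_um2[gid]
                area_errors.append(abs(dets[int(j)].area_um2 - truth) / truth)
                break
    tp = len(matches)
    fp = len(dets) - tp
    fn = len(gt.ld_centroids) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "f1": f1,
        "area_errors": np.array(area_errors), "matches": matches,
    }


# ---------------------------------------------------------------------------
# sidecar output
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, directory: str | Path) -> Path:
    """Write label maps as TIFFs and the rest as a JSON sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("nucleus_labels", "cell_labels", "ld_labels"):
        arr = getattr(gt, name)
        if arr is not None:
            tifffile.imwrite(directory / f"{name}.tif", arr.astype(np.uint16))
    side = {
        "ld_areas_um2": {str(k): v for k, v in gt.ld_areas_um2.items()},
        "ld_cell": {str(k): v for k, v in gt.ld_cell.items()},
        "planted_clusters": [sorted(c) for c in gt.planted_clusters],
        "planted_foci": [
            {
                "position": list(f.position),
                "intensity": f.intensity,
                "ld_ids": list(f.ld_ids),
                "at_contact_site": f.at_contact_site,
                "host_eligible": f.host_eligible,
            }
            for f in gt.planted_foci
        ],
        "event_log": [
            {
                "frame": e.frame,
                "time_s": e.time_s,
                "pair_id": e.pair_id,
                "kind": e.kind,
                "marker_positive": e.marker_positive,
                "marker_onset": e.marker_onset,
            }
            for e in gt.event_log
        ],
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(side, fh, indent=1)
    return directory
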