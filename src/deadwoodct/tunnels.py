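"""Classical segmentation of beetle tunnels in log CT volumes.

The pipeline follows a thresholding-plus-morphology recipe throughout:

1. **Wood detection** — hysteresis thresholding on the normalized volume
   (strong seeds grown into a weak mask), morphological closing and removal
   of small components yield the solid (bark + wood) mask.
2. **Bark separation** — per slice, the bark is the outer shell of the
   solid, found from a change point in the radial intensity profile (bark is
   less dense than the earlywood behind it).
3. **Cavity detection** — air-filled cavities appear dark and are found by
   the mirrored hysteresis rule inside the 2-D hole-filled hull.
4. **Cavity classification** — connected components (26-neighborhood) are
   split into shrinkage cracks (thin radial sheets touching the surface),
   drill holes (straight tubes in the auger radius band) and beetle tunnels
   (everything else), assigned to bark or wood by majority.
5. **Larva detection** — bright blobs kept only when connected to a tunnel
   and plausibly sized.
6. **Quantification** — tunnel voxels are counted separately for bark, wood
   and the complete log; virtual bark unrolling gives a radial surface view.

Refilled tunnels (frass-packed galleries) are intentionally not detected;
they resemble wood and contribute negligibly to cavity volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import ball

from .ctvolume import NormalizedVolume, ParameterError
from .labels import Label, LabelVolume
from .summary import VolumeSummary

logger = logging.getLogger(__name__)

#: 26-neighborhood in 3-D, used for all volumetric connected components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoLogFoundError(RuntimeError):
    """The solid-detection step produced an empty mask."""


def _slice_hull(solid: np.ndarray) -> np.ndarray:
    """Per-slice convex hull of the solid: the volume the intact log occupies.

    A plain hole filling would miss cavities that open to the surface
    (shrinkage cracks cut slits into the disc, drill holes enter from
    outside); the cross-section of a log is convex, so the convex hull
    closes those openings.
    """
    from skimage.morphology import convex_hull_image

    hull = np.zeros_like(solid)
    for z in range(solid.shape[0]):
        if solid[z].any():
            hull[z] = convex_hull_image(solid[z])
    return hull


def _interior_hull(solid: np.ndarray) -> np.ndarray:
    """Convex hull eroded in-plane by 2 voxels: the region where a dark voxel
    is genuinely interior. The erosion removes the sub-voxel slivers where
    the polygonal hull overshoots the rasterized disc boundary."""
    from skimage.morphology import disk

    return ndi.binary_erosion(_slice_hull(solid), structure=disk(2)[None])


@dataclass(frozen=True)
class HysteresisParams:
    """Two-threshold segmentation parameters (normalized units).

    For solid detection voxels >= ``high`` seed regions that grow through
    voxels >= ``low``; for cavity detection the rule is mirrored (voxels
    <= ``low`` seed regions growing through voxels <= ``high``).

    The exact thresholds used on the field data are not public; these
    defaults sit between air (0.0) and moist wood and are calibrated on
    phantoms.
    """

    low: float = 0.12
    high: float = 0.20
    #: optional closing of the solid mask; off by default — closing seals
    #: 1-2 voxel shrinkage cracks, which must stay visible to cavity detection
    closing_radius_vox: int = 0
    min_component_vox: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 1:
            raise ParameterError("need 0 <= low < high <= 1")


@dataclass(frozen=True)
class BarkParams:
    """Bark/wood boundary parameters.

    ``bark_value_max`` is the normalized intensity below which the radial
    median profile is considered bark (bark is less dense than earlywood);
    ``max_depth_mm`` caps the change-point search.
    """

    bark_value_max: float = 0.22
    max_depth_mm: float = 15.0


@dataclass(frozen=True)
class GeometryRules:
    """Shape-descriptor thresholds separating cracks and drillings from tunnels.

    Cavities are first split by local thickness: voxels deeper than
    ``core_min_depth_vox`` inside the cavity mask seed tube-like components
    which absorb their boundary shell; the thin residual (1-voxel sheets —
    crack candidates) forms separate components. This keeps a shrinkage
    crack separable from a beetle tunnel even where the two intersect.
    """

    crack_planarity_min: float = 3.0
    crack_radial_alignment_min: float = 0.6
    crack_max_radius_mm: float = 1.0
    drill_straightness_min: float = 0.92
    drill_radius_mm: tuple[float, float] = (2.0, 6.0)
    min_component_vox: int = 8
    core_min_depth_vox: float = 1.5
    shell_assign_max_vox: float = 3.0


@dataclass
class TissueMasks:
    """Mutually exclusive background / bark / wood masks for one volume."""

    background: np.ndarray
    bark: np.ndarray
    wood: np.ndarray
    log_axis_center: np.ndarray  # (n_slices, 2) per-slice (y, x) solid centroid

    @property
    def solid(self) -> np.ndarray:
        return self.bark | self.wood


@dataclass
class CavityComponent:
    """Shape descriptors of one connected air-filled cavity."""

    id: int
    voxel_count: int
    mean_radius_vox: float
    elongation: float
    planarity: float
    radial_alignment: float
    touches_surface: bool
    straightness: float
    compartment: str  # bark / wood / both
    classification: str = ""  # tunnel / crack / drilling


def detect_solid(vol: NormalizedVolume, params: HysteresisParams | None = None) -> np.ndarray:
    """Hysteresis-threshold the normalized volume into a solid (bark+wood) mask."""
    params = params or HysteresisParams()
    mask = apply_hysteresis_threshold(vol.values, params.low, params.high)
    if params.closing_radius_vox > 0:
        mask = ndi.binary_closing(mask, structure=ball(params.closing_radius_vox))
    if params.min_component_vox > 1:
        lab, n = ndi.label(mask, structure=STRUCT_26)
        if n:
            counts = np.bincount(lab.ravel())
            keep = counts >= params.min_component_vox
            keep[0] = False
            mask = keep[lab]
    if not mask.any():
        raise NoLogFoundError("no solid voxels above the hysteresis thresholds")
    return mask


def split_bark_wood(
    solid: np.ndarray, vol: NormalizedVolume, bark_params: BarkParams | None = None
) -> TissueMasks:
    """Partition the solid into an outer bark shell and inner wood, per slice.

    For each slice the Euclidean distance from the *outer* log surface (the
    boundary of the hole-filled hull, so interior cavities do not count as
    boundary) is binned into integer depths; the bark depth is the largest
    run of consecutive outer depths whose median intensity stays in the bark
    band. Slices with an empty solid yield empty masks (logged).
    """
    bark_params = bark_params or BarkParams()
    px = float(np.mean(vol.pixel_spacing))
    max_depth_vox = max(int(round(bark_params.max_depth_mm / px)), 1)
    nz = solid.shape[0]
    bark = np.zeros_like(solid)
    centers = np.full((nz, 2), np.nan)
    hull3d = _slice_hull(solid)
    for z in range(nz):
        sl = solid[z]
        if not sl.any():
            logger.info("split_bark_wood: slice %d has no solid voxels", z)
            continue
        centers[z] = ndi.center_of_mass(sl)
        edt = ndi.distance_transform_edt(hull3d[z], sampling=vol.pixel_spacing)
        depth_bin = np.minimum((edt / px).astype(int), max_depth_vox + 1)
        vals = vol.values[z]
        depth = -1
        for d in range(0, max_depth_vox + 1):
            sel = sl & (depth_bin == d)
            if not sel.any():
                # hull overshoot: shallow bins can hold no solid voxel
                continue
            if np.median(vals[sel]) > bark_params.bark_value_max:
                break
            depth = d
        if depth >= 0:
            bark[z] = sl & (depth_bin <= depth)
    wood = solid & ~bark
    return TissueMasks(background=~solid, bark=bark, wood=wood, log_axis_center=centers)


def detect_cavities(
    vol: NormalizedVolume, tissues: TissueMasks, params: HysteresisParams | None = None
) -> np.ndarray:
    """Dark-voxel hysteresis inside the hole-filled hull of the solid.

    Seeds are voxels <= ``low`` (confidently air); they grow through voxels
    <= ``high``. Only voxels inside the per-slice convex hull but outside
    the solid can be cavities, which keeps outside air out of the mask.
    """
    params = params or HysteresisParams()
    solid = tissues.solid
    interior = _interior_hull(solid) & ~solid
    candidate = (vol.values <= params.high) & interior
    seeds = (vol.values <= params.low) & interior
    lab, n = ndi.label(candidate, structure=STRUCT_26)
    if n == 0:
        return np.zeros_like(solid)
    seeded = np.unique(lab[seeds])
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    keep[0] = False
    return keep[lab]


def _split_components(cavities: np.ndarray, rules: GeometryRules) -> tuple[np.ndarray, int]:
    """Label cavities into thickness-split 26-connected components.

    Tube cores (interior depth >= ``core_min_depth_vox``) are labeled first
    and absorb cavity voxels within ``shell_assign_max_vox`` of a core; the
    remaining thin voxels form their own components.
    """
    depth = ndi.distance_transform_edt(cavities)
    cores = depth >= rules.core_min_depth_vox
    lab = np.zeros(cavities.shape, dtype=np.int32)
    n = 0
    if cores.any():
        core_lab, n = ndi.label(cores, structure=STRUCT_26)
        dist_to_core, inds = ndi.distance_transform_edt(~cores, return_indices=True)
        shell = cavities & (dist_to_core <= rules.shell_assign_max_vox)
        lab[shell] = core_lab[tuple(ind[shell] for ind in inds)]
    residual = cavities & (lab == 0)
    if residual.any():
        res_lab, m = ndi.label(residual, structure=STRUCT_26)
        lab[residual] = res_lab[residual] + n
        n += m
    return lab, n


def _nearest_compartment(cavities: np.ndarray, tissues: TissueMasks) -> np.ndarray:
    """Per-voxel code (1=bark, 2=wood) of the nearest tissue voxel."""
    tissue = np.zeros(cavities.shape, dtype=np.uint8)
    tissue[tissues.bark] = 1
    tissue[tissues.wood] = 2
    if not tissue.any():
        return np.full(cavities.shape, 2, dtype=np.uint8)
    idx = ndi.distance_transform_edt(tissue == 0, return_distances=False, return_indices=True)
    return tissue[tuple(idx)]


def _component_descriptors(
    coords_mm: np.ndarray, mask: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[float, float, float, np.ndarray, float]:
    """PCA shape descriptors of one component (coords in mm, z/y/x order)."""
    centered = coords_mm - coords_mm.mean(axis=0)
    cov = centered.T @ centered / max(len(coords_mm) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals[::-1], 1e-9)
    evecs = evecs[:, ::-1]
    elongation = float(np.sqrt(evals[0] / evals[1]))
    planarity = float(np.sqrt(evals[1] / evals[2]))
    normal = evecs[:, 2]  # normal of the principal plane

    # straightness: polyline through centroids of bins along the main axis
    proj = centered @ evecs[:, 0]
    span = proj.max() - proj.min()
    step = max(float(np.min(spacing)) * 1.5, span / 64 if span > 0 else 1.0)
    if span <= step:
        straightness = 1.0
    else:
        bins = ((proj - proj.min()) / step).astype(int)
        order = np.argsort(bins)
        uniq, starts = np.unique(bins[order], return_index=True)
        pts = np.array(
            [coords_mm[order[s:e]].mean(axis=0)
             for s, e in zip(starts, list(starts[1:]) + [len(order)])]
        )
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        end_to_end = np.linalg.norm(pts[-1] - pts[0])
        straightness = float(np.clip(end_to_end / seglen, 1e-6, 1.0)) if seglen > 0 else 1.0
    return elongation, planarity, straightness, normal, float(span)


def classify_cavities(
    cavities: np.ndarray,
    tissues: TissueMasks,
    spacing: tuple[float, float, float],
    rules: GeometryRules | None = None,
) -> tuple[np.ndarray, list[CavityComponent]]:
    """Split cavity components into tunnels, cracks and drill holes.

    Components are 26-connected. A component is a *crack* when it is a thin
    radially aligned sheet touching the log surface, a *drilling* when it is
    a straight tube in the auger radius band, and a beetle *tunnel*
    otherwise. Tunnel voxels inherit the compartment (bark/wood) of their
    nearest tissue voxel; the component's majority compartment is recorded.

    Returns a uint8 label fragment (codes from :class:`Label`, zero
    elsewhere) and the per-component descriptor list.
    """
    rules = rules or GeometryRules()
    out = np.zeros(cavities.shape, dtype=np.uint8)
    comps: list[CavityComponent] = []
    if not cavities.any():
        return out, comps
    lab, n = _split_components(cavities, rules)
    if n == 0:
        return out, comps
    sz, sy, sx = spacing
    comp_of_voxel = _nearest_compartment(cavities, tissues)
    # surface contact: cavity voxel adjacent to outside-of-hull background
    # (same eroded hull as cavity detection, so rim cavities register)
    outside = ~_interior_hull(tissues.solid)
    near_outside = ndi.binary_dilation(outside, structure=STRUCT_26)
    edt_vox = ndi.distance_transform_edt(cavities)

    slices = ndi.find_objects(lab)
    for i, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        sub = lab[slc] == i
        count = int(sub.sum())
        zz, yy, xx = np.nonzero(sub)
        zz = zz + slc[0].start
        yy = yy + slc[1].start
        xx = xx + slc[2].start
        coords_mm = np.stack([zz * sz, yy * sy, xx * sx], axis=1)
        elong, planarity, straightness, normal, _ = _component_descriptors(
            coords_mm, sub, (sz, sy, sx)
        )
        mean_radius_vox = float(edt_vox[zz, yy, xx].max())
        radius_mm = mean_radius_vox * float(np.mean((sy, sx)))
        touches = bool(near_outside[zz, yy, xx].any())

        # radial alignment: cracks are planes containing the axial and radial
        # directions, so their normal points tangentially (in-plane, and
        # perpendicular to the radial direction at the centroid)
        zc = int(round(zz.mean()))
        center = tissues.log_axis_center[min(zc, len(tissues.log_axis_center) - 1)]
        if np.any(np.isnan(center)):
            radial_alignment = 0.0
        else:
            radial = np.array([0.0, yy.mean() - center[0], xx.mean() - center[1]])
            radial[1] *= sy
            radial[2] *= sx
            nr = np.linalg.norm(radial[1:])
            if nr > 0:
                tangential = np.array([0.0, -radial[2], radial[1]]) / nr
                radial_alignment = float(abs(normal @ tangential))
            else:
                radial_alignment = 0.0

        votes = np.bincount(comp_of_voxel[zz, yy, xx], minlength=3)
        if votes[1] and votes[2]:
            compartment = "both"
        elif votes[1]:
            compartment = "bark"
        else:
            compartment = "wood"
        majority = Label.TUNNEL_BARK if votes[1] > votes[2] else Label.TUNNEL_WOOD

        if count < rules.min_component_vox:
            cls = "tunnel"
        elif (
            planarity >= rules.crack_planarity_min
            and radial_alignment >= rules.crack_radial_alignment_min
            and touches
            and radius_mm <= rules.crack_max_radius_mm
        ):
            cls = "crack"
        elif (
            straightness >= rules.drill_straightness_min
            and rules.drill_radius_mm[0] <= radius_mm <= rules.drill_radius_mm[1]
        ):
            cls = "drilling"
        else:
            cls = "tunnel"

        if cls == "crack":
            out[zz, yy, xx] = int(Label.CRACK)
        elif cls == "drilling":
            out[zz, yy, xx] = int(Label.DRILLING)
        else:
            vox_labels = np.where(
                comp_of_voxel[zz, yy, xx] == 1, int(Label.TUNNEL_BARK), int(Label.TUNNEL_WOOD)
            )
            out[zz, yy, xx] = vox_labels.astype(np.uint8)
            # keep component-majority assignment for single-compartment comps
            if compartment != "both":
                out[zz, yy, xx] = int(majority)
        comps.append(
            CavityComponent(
                id=i,
                voxel_count=count,
                mean_radius_vox=mean_radius_vox,
                elongation=elong,
                planarity=planarity,
                radial_alignment=radial_alignment,
                touches_surface=touches,
                straightness=straightness,
                compartment=compartment,
                classification=cls,
            )
        )
    return out, comps


def detect_larvae(
    vol: NormalizedVolume,
    tunnel_mask: np.ndarray,
    larva_band: tuple[float, float] = (0.40, 0.47),
    size_range_vox: tuple[int, int] = (30, 100_000),
) -> np.ndarray:
    """Bright blobs kept only when 26-connected to a tunnel and sized like larvae.

    The connectivity requirement prevents moisture-rich wood from being
    classified as larvae.
    """
    bright = (vol.values >= larva_band[0]) & (vol.values <= larva_band[1])
    lab, n = ndi.label(bright, structure=STRUCT_26)
    if n == 0:
        return np.zeros_like(tunnel_mask)
    near_tunnel = ndi.binary_dilation(tunnel_mask, structure=STRUCT_26)
    counts = np.bincount(lab.ravel())
    touching = np.unique(lab[near_tunnel])
    keep = np.zeros(n + 1, dtype=bool)
    for i in touching:
        if i and size_range_vox[0] <= counts[i] <= size_range_vox[1]:
            keep[i] = True
    return keep[lab]


def quantify_tunnel_volume(
    labels: LabelVolume,
    tissues: TissueMasks,
    include_larvae: bool = True,
    log_id: str = "",
) -> VolumeSummary:
    """Count tunnel voxels per compartment and convert to relative volumes.

    Larvae occupy excavated space and count toward the tunnel volume of
    their compartment by default.
    """
    c = labels.counts()
    tunnel_bark = c[Label.TUNNEL_BARK]
    tunnel_wood = c[Label.TUNNEL_WOOD]
    if include_larvae and c[Label.LARVA]:
        larva = labels.mask(Label.LARVA)
        comp = _nearest_compartment(larva, tissues)
        tunnel_bark += int((larva & (comp == 1)).sum())
        tunnel_wood += int((larva & (comp == 2)).sum())
    return VolumeSummary(
        voxel_volume_mm3=labels.voxel_volume_mm3,
        tunnel_bark_vox=tunnel_bark,
        tunnel_wood_vox=tunnel_wood,
        bark_vox=c[Label.BARK],
        wood_vox=c[Label.WOOD],
        larva_vox=c[Label.LARVA],
        crack_vox=c[Label.CRACK],
        drilling_vox=c[Label.DRILLING],
        decay_vox=c[Label.DECAY],
        log_id=log_id,
        larvae_counted_as_tunnel=include_larvae,
    )


def unroll_bark(
    source: np.ndarray,
    tissues: TissueMasks,
    angular_samples: int = 360,
    mode: str = "class_priority",
) -> np.ndarray:
    """Sample the bark shell onto a (slice, angle) image — virtual bark unrolling.

    For every slice and angle the radial ray through the bark shell is
    sampled. ``mode='max'`` takes the maximum value along the ray (for HU or
    normalized input); ``mode='class_priority'`` picks the most informative
    class (tunnel > larva > crack > drilling > bark) for label input. Slices
    without bark yield background rows.
    """
    nz = source.shape[0]
    out = np.zeros((nz, angular_samples), dtype=source.dtype)
    angles = np.linspace(0, 2 * np.pi, angular_samples, endpoint=False)
    priority = [Label.TUNNEL_BARK, Label.TUNNEL_WOOD, Label.LARVA, Label.CRACK,
                Label.DRILLING, Label.BARK]
    for z in range(nz):
        bark = tissues.bark[z]
        if not bark.any():
            continue
        cy, cx = tissues.log_axis_center[z]
        # radial extent of the bark shell on this slice
        yy, xx = np.nonzero(bark)
        rr = np.hypot(yy - cy, xx - cx)
        r_in, r_out = rr.min() - 1.5, rr.max() + 1.5
        radii = np.arange(max(r_in, 0), r_out + 0.5, 0.5)
        ys = cy + radii[None, :] * np.cos(angles)[:, None]
        xs = cx + radii[None, :] * np.sin(angles)[:, None]
        coords = np.stack([ys, xs])
        samples = ndi.map_coordinates(source[z], coords, order=0, mode="constant", cval=0)
        in_bark_band = ndi.map_coordinates(
            ndi.binary_dilation(bark).astype(np.uint8), coords, order=0, mode="constant"
        ).astype(bool)
        if mode == "max":
            vals = np.where(in_bark_band, samples, np.min(source[z]))
            out[z] = vals.max(axis=1)
        else:
            row = np.zeros(angular_samples, dtype=source.dtype)
            for lab in reversed(priority):
                hit = (samples == int(lab)) & in_bark_band
                has = hit.any(axis=1)
                row[has] = int(lab)
            out[z] = row
    return out


@dataclass
class TunnelSegmentation:
    """Bundle returned by the end-to-end tunnel pipeline."""

    labels: LabelVolume
    tissues: TissueMasks
    summary: VolumeSummary
    components: list[CavityComponent] = field(default_factory=list)


def segment_log(
    vol: NormalizedVolume,
    hysteresis: HysteresisParams | None = None,
    bark_params: BarkParams | None = None,
    rules: GeometryRules | None = None,
    larva_band: tuple[float, float] = (0.40, 0.47),
    larva_size_vox: tuple[int, int] = (30, 100_000),
    include_larvae: bool = True,
    log_id: str = "",
) -> TunnelSegmentation:
    """Run the full tunnel pipeline on a normalized volume."""
    solid = detect_solid(vol, hysteresis)
    tissues = split_bark_wood(solid, vol, bark_params)
    cavities = detect_cavities(vol, tissues, hysteresis)
    fragment, comps = classify_cavities(
        cavities, tissues, (vol.slice_thickness, *vol.pixel_spacing), rules
    )
    tunnel_mask = (fragment == int(Label.TUNNEL_BARK)) | (fragment == int(Label.TUNNEL_WOOD))
    larvae = detect_larvae(vol, tunnel_mask, larva_band, larva_size_vox)

    classes = np.zeros(vol.shape, dtype=np.uint8)
    classes[tissues.bark] = int(Label.BARK)
    classes[tissues.wood] = int(Label.WOOD)
    nonzero = fragment > 0
    classes[nonzero] = fragment[nonzero]
    classes[larvae] = int(Label.LARVA)
    labels = LabelVolume(
        classes=classes,
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
    )
    summary = quantify_tunnel_volume(labels, tissues, include_larvae, log_id=log_id)
    return TunnelSegmentation(labels=labels, tissues=tissues, summary=summary, components=comps)


def export_tunnel_coordinates(labels: LabelVolume) -> "pd.DataFrame":
    """Tunnel voxel coordinates (mm) for 3-D rendering, one row per voxel."""
    import pandas as pd

    mask = labels.mask(Label.TUNNEL_BARK, Label.TUNNEL_WOOD)
    zz, yy, xx = np.nonzero(mask)
    py, px = labels.pixel_spacing
    return pd.DataFrame(
        {
            "z_mm": zz * labels.slice_thickness,
            "y_mm": yy * py,
            "x_mm": xx * px,
            "compartment": np.where(
                labels.classes[zz, yy, xx] == int(Label.TUNNEL_BARK), "bark", "wood"
            ),
        }
    )
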