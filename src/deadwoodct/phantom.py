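"""Synthetic deadwood CT phantoms and a simulated mesocosm experiment.

A phantom is a cylindrical Norway-spruce log carved into a voxel grid with
known per-voxel labels: a bark annulus around concentric early/latewood
rings, air-filled beetle galleries (tortuous random-walk tubes, either
penetrating the sapwood like wood-borer larvae or confined to the bark/
cambium shell like bark beetles), radial shrinkage cracks reaching in from
the surface, straight auger drill holes, bright larvae attached to
galleries, and fungal-decay regions that are darker or brighter than sound
wood, optionally with the perpendicular (cuboidal) crack systems typical of
brown rot. Gaussian HU noise is added after the labels are recorded, so the
label volume is exact ground truth.

The simulated experiment mirrors the mesocosm design used in the field:
61 mesocosms with two logs each (122 logs), allocated 26 / 20 / 15 to
control, bark-beetle and wood-borer treatments, with disc-based dry-mass
records whose subsampling error is modelled explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .ctvolume import CTVolume, ParameterError
from .labels import Label, LabelVolume
from .summary import VolumeSummary, summarize_labels


@dataclass
class LogPhantomSpec:
    """Parameter bundle from which a labeled log phantom is carved.

    Geometry defaults mirror the field logs (50 cm spruce logs of 16-20 cm
    diameter scanned at 0.29 mm pixel spacing / 0.67 mm slices); structure
    counts default to an undisturbed log and are set per scenario. HU levels
    follow the CT convention (air -1000, water 0); only their ordering
    air < bark < earlywood < latewood < larva is meaningful.
    """

    length_slices: int = 746
    radius_mm: float = 90.0
    bark_thickness_mm: float = 5.0
    ring_period_mm: float = 2.5
    pixel_spacing_mm: tuple[float, float] = (0.29, 0.29)
    slice_thickness_mm: float = 0.67
    margin_vox: int = 6

    hu_earlywood: float = -400.0
    hu_latewood: float = -100.0
    hu_bark: float = -500.0
    hu_air: float = -1000.0
    hu_larva: float = 60.0

    tunnel_count: int = 0  # wood-borer-style galleries penetrating sapwood
    bark_tunnel_count: int = 0  # bark-beetle-style galleries in the bark shell
    tunnel_radius_mm: tuple[float, float] = (0.8, 1.6)
    tunnel_length_mm: tuple[float, float] = (30.0, 80.0)
    tunnel_tortuosity: float = 0.25  # 0 = straight, 1 = fully random walk

    crack_count: int = 0
    crack_max_depth: float = 0.6  # fraction of the radius reached from surface
    drilling_count: int = 0
    drilling_radius_mm: float = 4.0  # 8 mm auger

    larva_count: int = 0
    larva_length_mm: float = 18.0
    larva_width_mm: float = 4.0

    decay_patch_count: int = 0
    decay_contrast_hu: float = -150.0  # signed: negative = darker than wood
    decay_radius_mm: tuple[float, float] = (8.0, 20.0)
    decay_crack_system: bool = False

    noise_sigma_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ParameterError("radius and slice thickness must be positive")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ParameterError("pixel spacing must be positive")
        if not 0 <= self.bark_thickness_mm < self.radius_mm:
            raise ParameterError("bark thickness must be in [0, radius)")
        for name in ("tunnel_count", "bark_tunnel_count", "crack_count",
                     "drilling_count", "larva_count", "decay_patch_count",
                     "length_slices"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.tunnel_radius_mm[0] > self.tunnel_radius_mm[1]:
            raise ParameterError("tunnel_radius_mm range inverted")
        if self.tunnel_radius_mm[1] >= self.radius_mm - self.bark_thickness_mm:
            raise ParameterError("tunnel radius does not fit inside the wood")
        if not 0 <= self.crack_max_depth <= 1:
            raise ParameterError("crack_max_depth is a fraction of the radius")
        if self.noise_sigma_hu < 0:
            raise ParameterError("noise_sigma_hu must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        py, px = self.pixel_spacing_mm
        ny = 2 * (math.ceil(self.radius_mm / py) + self.margin_vox)
        nx = 2 * (math.ceil(self.radius_mm / px) + self.margin_vox)
        return (self.length_slices, ny, nx)


def _unit(vec: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(vec)
    return vec / n if n > 0 else np.array([0.0, 0.0, 1.0])


class _Carver:
    """Shared geometry helpers over the (z, y, x) grid, in mm coordinates."""

    def __init__(self, spec: LogPhantomSpec):
        self.spec = spec
        nz, ny, nx = spec.grid_shape
        py, px = spec.pixel_spacing_mm
        self.spacing = np.array([spec.slice_thickness_mm, py, px])
        self.center = np.array([(ny - 1) / 2 * py, (nx - 1) / 2 * px])
        y_mm = np.arange(ny) * py - self.center[0]
        x_mm = np.arange(nx) * px - self.center[1]
        self.yy, self.xx = np.meshgrid(y_mm, x_mm, indexing="ij")
        self.rr = np.hypot(self.yy, self.xx)
        self.theta = np.arctan2(self.xx, self.yy)  # angle from +y toward +x
        self.shape = (nz, ny, nx)

    def stamp_ball(self, hu, labels, pos_mm, radius_mm, new_hu, label_of):
        """Set voxels within radius of pos to new_hu / a label, in-place.

        ``label_of`` maps the previous label to the new one (or None to keep).
        Returns the number of voxels changed.
        """
        lo = np.maximum(np.floor((pos_mm - radius_mm) / self.spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((pos_mm + radius_mm) / self.spacing).astype(int) + 1,
            np.array(self.shape),
        )
        if np.any(lo >= hi):
            return 0
        zz = (np.arange(lo[0], hi[0]) * self.spacing[0] - pos_mm[0]) ** 2
        yy = (np.arange(lo[1], hi[1]) * self.spacing[1] - pos_mm[1]) ** 2
        xx = (np.arange(lo[2], hi[2]) * self.spacing[2] - pos_mm[2]) ** 2
        inside = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= radius_mm**2
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        lab = labels[sub]
        changed = 0
        for old, new in label_of.items():
            sel = inside & (lab == int(old))
            lab[sel] = int(new)
            hu[sub][sel] = new_hu
            changed += int(sel.sum())
        return changed


def generate_phantom(
    spec: LogPhantomSpec, seed: int | None = None
) -> tuple[CTVolume, LabelVolume]:
    """Carve a labeled log phantom. Deterministic given (spec, seed).

    Returns the HU volume (with noise) and the exact label volume (recorded
    before noise). ``seed`` defaults to ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    geo = _Carver(spec)
    nz, ny, nx = geo.shape

    wood2d = geo.rr <= spec.radius_mm - spec.bark_thickness_mm
    solid2d = geo.rr <= spec.radius_mm
    bark2d = solid2d & ~wood2d

    # annual rings: outer ~30% of each ring period is the dense latewood band
    ring_phase = np.mod(geo.rr / spec.ring_period_mm, 1.0)
    hu2d = np.full((ny, nx), spec.hu_air, dtype=np.float32)
    hu2d[wood2d] = np.where(ring_phase[wood2d] < 0.7, spec.hu_earlywood, spec.hu_latewood)
    hu2d[bark2d] = spec.hu_bark

    lab2d = np.zeros((ny, nx), dtype=np.uint8)
    lab2d[bark2d] = int(Label.BARK)
    lab2d[wood2d] = int(Label.WOOD)

    hu = np.broadcast_to(hu2d, (nz, ny, nx)).copy()
    labels = np.broadcast_to(lab2d, (nz, ny, nx)).copy()

    tunnel_ends = _carve_tunnels(spec, geo, rng, hu, labels)
    _carve_cracks(spec, geo, rng, hu, labels)
    _carve_drillings(spec, geo, rng, hu, labels)
    _carve_larvae(spec, geo, rng, hu, labels, tunnel_ends)
    _carve_decay(spec, geo, rng, hu, labels)

    if spec.noise_sigma_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape).astype(np.float32)

    vol = CTVolume(
        voxels=hu.astype(np.float32),
        pixel_spacing=spec.pixel_spacing_mm,
        slice_thickness=spec.slice_thickness_mm,
        meta={"phantom": "1", "seed": str(spec.seed if seed is None else seed)},
    )
    labvol = LabelVolume(
        classes=labels,
        pixel_spacing=spec.pixel_spacing_mm,
        slice_thickness=spec.slice_thickness_mm,
    )
    return vol, labvol


def _carve_tunnels(spec, geo: _Carver, rng, hu, labels) -> list[np.ndarray]:
    """Random-walk galleries; returns centerline sample points for larvae."""
    carve_into = {Label.BARK: Label.TUNNEL_BARK, Label.WOOD: Label.TUNNEL_WOOD,
                  Label.DECAY: Label.TUNNEL_WOOD}
    nz = geo.shape[0]
    z_max_mm = (nz - 1) * spec.slice_thickness_mm
    ends: list[np.ndarray] = []
    step = min(geo.spacing)
    wood_r = spec.radius_mm - spec.bark_thickness_mm

    for kind in ["wood"] * spec.tunnel_count + ["bark"] * spec.bark_tunnel_count:
        r_t = rng.uniform(*spec.tunnel_radius_mm)
        length = rng.uniform(*spec.tunnel_length_mm)
        n_steps = max(int(length / step), 1)
        if kind == "wood":
            # start well inside the sapwood, wander with the set tortuosity
            rho = rng.uniform(0, 0.6 * wood_r)
            ang = rng.uniform(0, 2 * np.pi)
            pos = np.array(
                [rng.uniform(0.2, 0.8) * z_max_mm,
                 geo.center[0] + rho * np.cos(ang),
                 geo.center[1] + rho * np.sin(ang)]
            )
            direction = _unit(rng.normal(size=3))
            for _ in range(n_steps):
                geo_pos = pos.copy()
                geo.stamp_ball(hu, labels, geo_pos, r_t, spec.hu_air, carve_into)
                if spec.tunnel_tortuosity > 0:
                    direction = _unit(
                        (1 - spec.tunnel_tortuosity) * direction
                        + spec.tunnel_tortuosity * rng.normal(size=3)
                    )
                pos = pos + step * direction
                # reflect off the wood boundary and the slice range
                radial = pos[1:] - geo.center
                rho_now = np.linalg.norm(radial)
                limit = wood_r - r_t - step
                if rho_now > limit > 0:
                    nrm = radial / rho_now
                    d_in = direction[1:]
                    direction[1:] = d_in - 2 * np.dot(d_in, nrm) * nrm
                    pos[1:] = geo.center + nrm * limit
                if pos[0] < r_t or pos[0] > z_max_mm - r_t:
                    direction[0] = -direction[0]
                    pos[0] = np.clip(pos[0], r_t, z_max_mm - r_t)
        else:
            # bark gallery: fixed radial depth mid-bark, walk in (z, angle)
            rho = spec.radius_mm - spec.bark_thickness_mm / 2
            ang = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(0.1, 0.9) * z_max_mm
            heading = rng.uniform(0, 2 * np.pi)  # in the (z, arc) plane
            for _ in range(n_steps):
                pos = np.array(
                    [z, geo.center[0] + rho * np.cos(ang), geo.center[1] + rho * np.sin(ang)]
                )
                geo.stamp_ball(hu, labels, pos, r_t, spec.hu_air, carve_into)
                if spec.tunnel_tortuosity > 0:
                    heading += spec.tunnel_tortuosity * rng.normal(0, 0.8)
                z += step * np.cos(heading)
                ang += step * np.sin(heading) / rho
                if z < r_t or z > z_max_mm - r_t:
                    heading = np.pi - heading
                    z = np.clip(z, r_t, z_max_mm - r_t)
        ends.append(pos)
    return ends


def _carve_cracks(spec, geo: _Carver, rng, hu, labels) -> None:
    nz = geo.shape[0]
    carve = (int(Label.BARK), int(Label.WOOD), int(Label.DECAY))
    for _ in range(spec.crack_count):
        ang = rng.uniform(0, 2 * np.pi)
        depth = rng.uniform(0.5, 1.0) * spec.crack_max_depth * spec.radius_mm
        width = rng.uniform(1.0, 2.0) * float(np.mean(spec.pixel_spacing_mm))
        z0 = rng.integers(0, max(nz // 2, 1))
        z1 = rng.integers(min(z0 + nz // 2, nz - 1), nz)
        # perpendicular distance to the radial ray at angle `ang`
        d_perp = np.abs(geo.rr * np.sin(geo.theta - ang))
        along = geo.rr * np.cos(geo.theta - ang)
        in_wedge = (
            (d_perp <= width / 2)
            & (along > spec.radius_mm - depth)
            & (geo.rr <= spec.radius_mm)
        )
        sub = labels[z0 : z1 + 1]
        sel = in_wedge[None] & np.isin(sub, carve)
        sub[sel] = int(Label.CRACK)
        hu[z0 : z1 + 1][sel] = spec.hu_air


def _carve_drillings(spec, geo: _Carver, rng, hu, labels) -> None:
    """Straight auger holes, perpendicular to the stem axis, surface inward."""
    nz = geo.shape[0]
    carve_into = {Label.BARK: Label.DRILLING, Label.WOOD: Label.DRILLING,
                  Label.DECAY: Label.DRILLING}
    step = min(geo.spacing)
    for _ in range(spec.drilling_count):
        ang = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(0.15, 0.85) * (nz - 1) * spec.slice_thickness_mm
        depth = rng.uniform(0.4, 0.7) * spec.radius_mm
        direction = np.array([0.0, -np.cos(ang), -np.sin(ang)])
        pos = np.array(
            [z, geo.center[0] + spec.radius_mm * np.cos(ang),
             geo.center[1] + spec.radius_mm * np.sin(ang)]
        )
        for _ in range(int(depth / step)):
            geo.stamp_ball(hu, labels, pos, spec.drilling_radius_mm, spec.hu_air, carve_into)
            pos = pos + step * direction


def _carve_larvae(spec, geo: _Carver, rng, hu, labels, tunnel_ends) -> None:
    if spec.larva_count == 0 or not tunnel_ends:
        return
    carve_into = {Label.TUNNEL_WOOD: Label.LARVA, Label.TUNNEL_BARK: Label.LARVA,
                  Label.WOOD: Label.LARVA, Label.BARK: Label.LARVA}
    half_len = spec.larva_length_mm / 2
    half_w = spec.larva_width_mm / 2
    n_balls = max(int(spec.larva_length_mm / half_w), 2)
    for i in range(spec.larva_count):
        center = tunnel_ends[int(rng.integers(0, len(tunnel_ends)))]
        axis = _unit(np.concatenate([[rng.normal(0, 0.3)], rng.normal(size=2)]))
        # ellipsoid approximated by a chain of balls along the body axis
        for t in np.linspace(-1, 1, n_balls):
            r_here = half_w * math.sqrt(max(1 - t**2, 0.05))
            geo.stamp_ball(hu, labels, center + t * half_len * axis, r_here,
                           spec.hu_larva, carve_into)


def _carve_decay(spec, geo: _Carver, rng, hu, labels) -> None:
    if spec.decay_patch_count == 0:
        return
    nz = geo.shape[0]
    wood_r = spec.radius_mm - spec.bark_thickness_mm
    hu_mean_wood = 0.7 * spec.hu_earlywood + 0.3 * spec.hu_latewood
    for _ in range(spec.decay_patch_count):
        r_patch = rng.uniform(*spec.decay_radius_mm)
        rho = rng.uniform(0, max(wood_r - r_patch * 0.5, 1.0))
        ang = rng.uniform(0, 2 * np.pi)
        cz = rng.uniform(0.1, 0.9) * (nz - 1) * spec.slice_thickness_mm
        cy = geo.center[0] + rho * np.cos(ang)
        cx = geo.center[1] + rho * np.sin(ang)
        # decay spreads preferentially along the grain: elongated in z
        zz = ((np.arange(nz) * spec.slice_thickness_mm - cz) / (2 * r_patch)) ** 2
        in_plane = ((geo.yy - (cy - geo.center[0])) ** 2 + (geo.xx - (cx - geo.center[1])) ** 2) / r_patch**2
        inside = zz[:, None, None] + in_plane[None] <= 1.0
        sel = inside & (labels == int(Label.WOOD))
        # decayed wood loses ring structure: flatten texture, shift density
        flat = hu_mean_wood + 0.25 * (hu[sel] - hu_mean_wood) + spec.decay_contrast_hu
        hu[sel] = flat
        labels[sel] = int(Label.DECAY)
        if spec.decay_crack_system:
            # cuboidal brown-rot clefts: dark planes on a ~4 mm grid, both
            # in-plane orientations, labeled decay (part of the decayed region)
            spacing_mm = 4.0
            gy = np.mod(geo.yy, spacing_mm) < float(spec.pixel_spacing_mm[0])
            gx = np.mod(geo.xx, spacing_mm) < float(spec.pixel_spacing_mm[1])
            cleft = inside & (gy | gx)[None] & (labels == int(Label.DECAY))
            hu[cleft] = -800.0


#: exact ground-truth volume summary of a phantom's labels
def true_volume_summary(labels: LabelVolume, include_larvae: bool = False,
                        log_id: str = "") -> VolumeSummary:
    return summarize_labels(labels, include_larvae=include_larvae, log_id=log_id)


# ---------------------------------------------------------------------------
# Simulated mesocosm experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentDesign:
    """Mesocosm counts per treatment; the field design by default."""

    control: int = 26
    bark_beetles: int = 20
    wood_borers: int = 15
    logs_per_mesocosm: int = 2

    def __post_init__(self) -> None:
        if min(self.control, self.bark_beetles, self.wood_borers) < 0:
            raise ParameterError("treatment counts must be >= 0")
        if self.logs_per_mesocosm < 1:
            raise ParameterError("logs_per_mesocosm must be >= 1")

    @property
    def mesocosm_count(self) -> int:
        return self.control + self.bark_beetles + self.wood_borers

    @property
    def log_count(self) -> int:
        return self.mesocosm_count * self.logs_per_mesocosm


@dataclass(frozen=True)
class GuildEffect:
    """Mean relative tunnel volume [%] a guild excavates per compartment.

    Bark beetles work the bark/cambium shell only; wood-borers tunnel into
    the sapwood and also excavate under the bark (pupal chambers).
    """

    tunnel_percent_bark: float = 0.0
    tunnel_percent_wood: float = 0.0

    def __post_init__(self) -> None:
        if self.tunnel_percent_bark < 0 or self.tunnel_percent_wood < 0:
            raise ParameterError("effect sizes must be >= 0")


@dataclass(frozen=True)
class ExperimentEffects:
    """Effect sizes and noise sources of the simulated experiment."""

    control: GuildEffect = GuildEffect(0.0, 0.0)
    bark_beetles: GuildEffect = GuildEffect(2.3, 0.0)
    wood_borers: GuildEffect = GuildEffect(2.0, 1.8)
    effect_cv: float = 0.5  # lognormal spread of per-log effects
    decay_percent_mean: float = 5.0  # decayed share of the wood compartment
    decay_cv: float = 0.5
    decay_density_loss: float = 0.2  # dry-mass fraction lost in decayed wood
    disc_heterogeneity_cv: float = 0.04  # within-log dry:fresh variability
    scale_resolution_g: float = 0.1

    def for_treatment(self, name: str) -> GuildEffect:
        return {"control": self.control, "bark_beetles": self.bark_beetles,
                "wood_borers": self.wood_borers}[name]


@dataclass
class SimulatedExperiment:
    """Per-log ground truth, mass records and renderable phantom specs."""

    design: TreatmentDesign
    effects: ExperimentEffects
    logs: pd.DataFrame
    specs: dict[str, LogPhantomSpec]

    def render_log(self, log_id: str) -> tuple[CTVolume, LabelVolume]:
        """Voxelize one log from its stored spec (deterministic)."""
        return generate_phantom(self.specs[log_id])

    def to_csv(self, path: str | Path) -> None:
        self.logs.to_csv(path, index=False)


# fresh Norway spruce: green density and dry:fresh mass ratio
_FRESH_DENSITY_G_MM3 = 850e-6
_DRY_FRESH_RATIO = 0.45
_DISC_LENGTH_MM = 30.0
_LOG_LENGTH_MM = 500.0


def simulate_experiment(
    design: TreatmentDesign | None = None,
    effects: ExperimentEffects | None = None,
    seed: int = 0,
    geometry: LogPhantomSpec | None = None,
) -> SimulatedExperiment:
    """Simulate the mesocosm experiment: true fractions, masses, specs.

    Per-log tunnel fractions are drawn from lognormal distributions around
    the treatment effect sizes; dry-mass loss is constructed from the mass
    of excavated voxels plus decay-degraded mass, so tunnel fraction and
    mass loss are positively correlated by construction. The disc-based
    initial dry-mass estimate carries within-log heterogeneity, so the
    estimator has realistic error (including negative apparent mass loss).

    ``geometry`` is the template phantom spec each log's spec derives from;
    pass a scaled-down template to keep rendered phantoms small.
    """
    design = design or TreatmentDesign()
    effects = effects or ExperimentEffects()
    geometry = geometry or LogPhantomSpec()
    rng = np.random.default_rng(seed)

    bark_frac = 1.0 - ((geometry.radius_mm - geometry.bark_thickness_mm) / geometry.radius_mm) ** 2
    wood_frac = 1.0 - bark_frac
    log_len_mm = geometry.length_slices * geometry.slice_thickness_mm
    log_volume_mm3 = math.pi * geometry.radius_mm**2 * log_len_mm
    mean_tunnel_vol = (
        math.pi * np.mean(geometry.tunnel_radius_mm) ** 2 * np.mean(geometry.tunnel_length_mm)
    )
    mean_decay_vol = 4 / 3 * math.pi * np.mean(geometry.decay_radius_mm) ** 3 * 2  # z-elongated

    def lognormal_around(mean: float, cv: float) -> float:
        if mean <= 0:
            return 0.0
        if cv <= 0:
            return mean
        sigma = math.sqrt(math.log(1 + cv**2))
        return float(rng.lognormal(math.log(mean) - sigma**2 / 2, sigma))

    treatments: list[str] = (
        ["control"] * design.control
        + ["bark_beetles"] * design.bark_beetles
        + ["wood_borers"] * design.wood_borers
    )
    rows = []
    specs: dict[str, LogPhantomSpec] = {}
    for m, treatment in enumerate(treatments, start=1):
        for j in range(design.logs_per_mesocosm):
            log_id = f"M{m:02d}L{j + 1}"
            eff = effects.for_treatment(treatment)
            tb = lognormal_around(eff.tunnel_percent_bark, effects.effect_cv)
            tw = lognormal_around(eff.tunnel_percent_wood, effects.effect_cv)
            decay = min(lognormal_around(effects.decay_percent_mean, effects.decay_cv), 80.0)
            total = (tb * bark_frac + tw * wood_frac)

            # ---- masses (grams) ----
            fresh_log = log_volume_mm3 * _FRESH_DENSITY_G_MM3 * rng.uniform(0.95, 1.05)
            true_ratio = _DRY_FRESH_RATIO * rng.uniform(0.95, 1.05)
            init_dry = fresh_log * true_ratio
            loss_frac = total / 100.0 + (decay / 100.0) * wood_frac * effects.decay_density_loss
            final_dry = init_dry * (1.0 - loss_frac)
            disc_ratio = true_ratio * (1.0 + rng.normal(0, effects.disc_heterogeneity_cv))
            fresh_disc = fresh_log * _DISC_LENGTH_MM / _LOG_LENGTH_MM * rng.uniform(0.9, 1.1)
            dry_disc = fresh_disc * disc_ratio

            def record(grams: float) -> float:
                q = effects.scale_resolution_g
                return round(grams / q) * q if q > 0 else grams

            fresh_log, fresh_disc, dry_disc, final_dry_meas = (
                record(fresh_log), record(fresh_disc), record(dry_disc), record(final_dry)
            )
            est_init = fresh_log / fresh_disc * dry_disc
            mass_loss_pct = 100.0 * (est_init - final_dry_meas) / est_init

            # ---- renderable spec with matching expected structure volume ----
            n_wood = int(round(tw / 100.0 * wood_frac * log_volume_mm3 / mean_tunnel_vol))
            n_bark = int(round(tb / 100.0 * bark_frac * log_volume_mm3 / mean_tunnel_vol))
            if tw > 0:
                n_wood = max(n_wood, 1)
            if tb > 0:
                n_bark = max(n_bark, 1)
            n_decay = int(round(decay / 100.0 * wood_frac * log_volume_mm3 / mean_decay_vol))
            specs[log_id] = replace(
                geometry,
                tunnel_count=n_wood,
                bark_tunnel_count=n_bark,
                decay_patch_count=n_decay,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(
                {
                    "log_id": log_id,
                    "mesocosm": m,
                    "treatment": treatment,
                    "true_tunnel_bark_percent": tb,
                    "true_tunnel_wood_percent": tw,
                    "true_tunnel_total_percent": total,
                    "true_decay_percent": decay,
                    "fresh_mass_log_g": fresh_log,
                    "fresh_mass_disc_g": fresh_disc,
                    "dry_mass_disc_g": dry_disc,
                    "measured_dry_mass_log_g": final_dry_meas,
                    "est_initial_dry_mass_g": est_init,
                    "mass_loss_percent": mass_loss_pct,
                }
            )
    return SimulatedExperiment(design, effects, pd.DataFrame(rows), specs)
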