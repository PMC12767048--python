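"""Synthetic vascular phantoms emulating the scanner's image exports.

Real acquisitions arrive as per-slice 8-bit rasters (density, speed,
axial-direction) produced by proprietary software from microbubble
tracks; no public data accompany them.  The phantom generator replaces
the scanner: it renders the same export products from an explicit list of
ground-truth vessel segments (geometry, full width, speed, axial flow
direction), so every downstream stage can be validated by recovering
known truth.

Vessels are straight constant-width segments with a capsule footprint
(all pixels whose center lies within width/2 of the segment) — the
simplest geometry with an analytic area, L*w + pi*(w/2)^2.  Where
vessels overlap in the speed or direction rasters, the vessel listed
later wins; the density raster is a plain union.

Geometry lives in physical µm; pixel (r, c) has its center at
((r + 0.5) * pixel_size, (c + 0.5) * pixel_size) with the row coordinate
increasing downward.  "Descending" flow (toward larger rows) marks
penetrating arterioles, "ascending" flow marks venules.

All randomness derives from one integer seed via numpy's SeedSequence
spawning: the cohort seed spawns one stream per animal, and each animal's
stream drives its geometry, speeds and NVC noise in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .flow import encode_speed
from .maps import BinaryMask, IntensityMap, RegionSet
from .nvc import NvcTrace, StimSchedule

DESCENDING = "descending"
ASCENDING = "ascending"


@dataclass(frozen=True)
class VesselSpec:
    """Ground truth for one straight vessel segment.

    ``endpoints`` are two (row_um, col_um) points; ``width_um`` is the
    full lumen diameter; ``velocity_mm_s`` the scalar blood speed carried
    by every pixel of the vessel; ``axial_direction`` the image-row sense
    of flow (descending = arteriole-like).
    """

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    width_um: float
    velocity_mm_s: float
    axial_direction: str = DESCENDING

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")
        if not 0 <= self.velocity_mm_s <= 100:
            raise ValueError("velocity_mm_s must lie in [0, 100]")
        if self.axial_direction not in (DESCENDING, ASCENDING):
            raise ValueError("axial_direction must be 'descending' or 'ascending'")
        (y0, x0), (y1, x1) = self.endpoints
        if y0 == y1 and x0 == x1:
            raise ValueError("endpoints must be distinct")

    @property
    def length_um(self) -> float:
        (y0, x0), (y1, x1) = self.endpoints
        return float(np.hypot(y1 - y0, x1 - x0))

    @property
    def analytic_area_um2(self) -> float:
        """Capsule area: rectangle plus the two end half-disks."""
        w = self.width_um
        return self.length_um * w + np.pi * (w / 2.0) ** 2


@dataclass(frozen=True)
class PhantomScene:
    """A set of ground-truth vessels on a fixed raster grid."""

    vessels: tuple[VesselSpec, ...]
    grid_shape: tuple[int, int]
    pixel_size_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vessels:
            raise ValueError("a scene needs at least one vessel")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        h_um = self.grid_shape[0] * self.pixel_size_um
        w_um = self.grid_shape[1] * self.pixel_size_um
        for i, v in enumerate(self.vessels):
            (y0, x0), (y1, x1) = v.endpoints
            r = v.width_um / 2.0
            if (
                min(y0, y1) - r < 0
                or min(x0, x1) - r < 0
                or max(y0, y1) + r > h_um
                or max(x0, x1) + r > w_um
            ):
                raise ValueError(
                    f"vessel {i} (capsule footprint) extends outside the "
                    f"{h_um:g} x {w_um:g} µm grid"
                )

    @property
    def extent_um(self) -> tuple[float, float]:
        return (
            self.grid_shape[0] * self.pixel_size_um,
            self.grid_shape[1] * self.pixel_size_um,
        )


def make_scene(
    specs: list[VesselSpec],
    grid_shape: tuple[int, int],
    pixel_size_um: float = 2.0,
    seed: int = 0,
) -> PhantomScene:
    """Validate vessel geometry against the grid and freeze it as a scene."""
    return PhantomScene(
        vessels=tuple(specs),
        grid_shape=tuple(grid_shape),
        pixel_size_um=pixel_size_um,
        seed=seed,
    )


def rasterize_vessel(spec: VesselSpec, scene: PhantomScene) -> np.ndarray:
    """Boolean footprint of one vessel: pixel centers within width/2 of
    the segment (computed only inside the capsule's bounding box)."""
    px = scene.pixel_size_um
    (y0, x0), (y1, x1) = spec.endpoints
    r = spec.width_um / 2.0
    r0 = max(int((min(y0, y1) - r) / px) - 1, 0)
    r1 = min(int((max(y0, y1) + r) / px) + 2, scene.grid_shape[0])
    c0 = max(int((min(x0, x1) - r) / px) - 1, 0)
    c1 = min(int((max(x0, x1) + r) / px) + 2, scene.grid_shape[1])
    rows = (np.arange(r0, r1) + 0.5) * px
    cols = (np.arange(c0, c1) + 0.5) * px
    py, pxs = np.meshgrid(rows, cols, indexing="ij")
    # distance from each pixel center to the segment
    dy, dx = y1 - y0, x1 - x0
    seg2 = dy * dy + dx * dx
    t = np.clip(((py - y0) * dy + (pxs - x0) * dx) / seg2, 0.0, 1.0)
    dist = np.hypot(py - (y0 + t * dy), pxs - (x0 + t * dx))
    out = np.zeros(scene.grid_shape, dtype=bool)
    out[r0:r1, c0:c1] = dist <= r
    return out


def scene_union_mask(scene: PhantomScene) -> BinaryMask:
    """Rasterized union of all vessel footprints (the mask oracle)."""
    union = np.zeros(scene.grid_shape, dtype=bool)
    for v in scene.vessels:
        union |= rasterize_vessel(v, scene)
    return BinaryMask(values=union, pixel_size_um=scene.pixel_size_um)


def render_density_map(scene: PhantomScene) -> IntensityMap:
    """Greyscale density export: vessel pixels 255, background 0."""
    values = scene_union_mask(scene).values.astype(np.uint8) * 255
    return IntensityMap(
        values=values, pixel_size_um=scene.pixel_size_um, modality="density"
    )


def render_speed_map(scene: PhantomScene) -> IntensityMap:
    """8-bit speed export: vessel pixels carry round(v * 2.55).

    Overlapping vessels are resolved in favor of the later-listed vessel.
    """
    values = np.zeros(scene.grid_shape, dtype=np.uint8)
    for v in scene.vessels:
        fp = rasterize_vessel(v, scene)
        values[fp] = encode_speed(v.velocity_mm_s)
    return IntensityMap(
        values=values, pixel_size_um=scene.pixel_size_um, modality="speed"
    )


def render_directional_map(scene: PhantomScene) -> IntensityMap:
    """RGB axial-direction export: descending flow pure red, ascending
    pure blue, background black; later-listed vessel wins on overlap."""
    values = np.zeros((*scene.grid_shape, 3), dtype=np.uint8)
    for v in scene.vessels:
        fp = rasterize_vessel(v, scene)
        color = (255, 0, 0) if v.axial_direction == DESCENDING else (0, 0, 255)
        values[fp] = color
    return IntensityMap(
        values=values, pixel_size_um=scene.pixel_size_um, modality="directional"
    )


# ---------------------------------------------------------------------------
# region layouts


def make_region_set(
    grid_shape: tuple[int, int],
    layout: dict[str, tuple[int, int, int, int]] | None = None,
    pixel_size_um: float = 2.0,
) -> RegionSet:
    """Build a RegionSet from named rectangular patches.

    ``layout`` maps region names to half-open pixel rectangles
    (row0, row1, col0, col1).  Rectangles must not overlap and must lie
    inside the grid; whole_brain is implicit (union of all patches).
    With no layout, three equal horizontal bands emulate the coronal
    arrangement: cortex on top, hippocampus, then subcortical white
    matter.
    """
    if layout is None:
        layout = horizontal_bands(grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int32)
    table: dict[int, str] = {}
    for i, (name, (r0, r1, c0, c1)) in enumerate(layout.items(), start=1):
        if not (0 <= r0 < r1 <= grid_shape[0] and 0 <= c0 < c1 <= grid_shape[1]):
            raise ValueError(f"region {name!r} rectangle lies outside the grid")
        patch = labels[r0:r1, c0:c1]
        if (patch != 0).any():
            raise ValueError(f"region {name!r} overlaps an earlier region")
        patch[:] = i
        table[i] = name
    return RegionSet(labels=labels, name_table=table, pixel_size_um=pixel_size_um)


def horizontal_bands(
    grid_shape: tuple[int, int],
    names: tuple[str, ...] = ("cortex", "hippocampus", "white_matter"),
) -> dict[str, tuple[int, int, int, int]]:
    """Equal-height full-width bands, top to bottom."""
    h, w = grid_shape
    band = h // len(names)
    return {
        name: (i * band, (i + 1) * band if i < len(names) - 1 else h, 0, w)
        for i, name in enumerate(names)
    }


# ---------------------------------------------------------------------------
# NVC trace simulation

#: baseline relative-CBV level, fixed so percent-change math is transparent
BASELINE_CBV = 100.0


@dataclass(frozen=True)
class HrfParams:
    """Gamma-variate hemodynamic response for one animal.

    ``amplitude_pct`` is the peak rCBV rise above baseline (in % of
    baseline), reached ``latency_s`` after stimulus onset;
    ``rise_shape`` is the gamma shape parameter (larger = steeper rise);
    ``noise_sd_pct`` additive white noise, in % of baseline.
    """

    amplitude_pct: float = 20.0
    latency_s: float = 5.0
    rise_shape: float = 3.0
    noise_sd_pct: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_pct < 0:
            raise ValueError("amplitude_pct must be nonnegative")
        if not self.latency_s > 0:
            raise ValueError("latency_s must be positive")
        if not self.rise_shape > 0:
            raise ValueError("rise_shape must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be nonnegative")


def gamma_variate(t_s: np.ndarray, latency_s: float, shape: float) -> np.ndarray:
    """Unit-peak gamma-variate kernel: (t/tp)^a * exp(a * (1 - t/tp)).

    Zero for t <= 0; exactly 1 at t = latency_s.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / latency_s
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def simulate_nvc_trace(
    hrf: HrfParams,
    schedule: StimSchedule = StimSchedule(),
    seed: int | np.random.Generator = 0,
    animal_id: str = "",
    group: str = "",
) -> NvcTrace:
    """Render a full stimulation session at baseline 100 arbitrary units.

    Each trial adds a gamma-variate response starting at stimulus onset
    and peaking ``amplitude_pct`` above baseline ``latency_s`` later,
    plus seeded white noise.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = np.arange(schedule.total_samples) * schedule.dt_s
    signal = np.full(t.shape, BASELINE_CBV)
    amp = BASELINE_CBV * hrf.amplitude_pct / 100.0
    for onset in schedule.trial_onsets_s():
        signal += amp * gamma_variate(t - onset, hrf.latency_s, hrf.rise_shape)
    if hrf.noise_sd_pct > 0:
        signal = signal + rng.normal(
            0.0, BASELINE_CBV * hrf.noise_sd_pct / 100.0, size=t.shape
        )
    return NvcTrace(samples=signal, schedule=schedule, animal_id=animal_id, group=group)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class AgedEffects:
    """Multiplicative aged-vs-young contrasts imposed on the ground truth."""

    coverage: float = 0.8
    width: float = 0.8
    velocity_hippocampus: float = 0.7
    velocity_cortex: float = 1.15
    velocity_white_matter: float = 1.0
    hrf_amplitude: float = 0.6
    hrf_latency: float = 1.5
    arteriole_fraction: float = 0.8

    @classmethod
    def none(cls) -> "AgedEffects":
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CohortParams:
    """Stated world for a young-vs-aged phantom cohort.

    Young-group means: target coverage fraction, log-normal vessel widths
    (median ``width_median_um``, log-sd ``width_sigma``), per-region mean
    speeds, HRF parameters, and the cortical arteriole area fraction.
    Between-animal variability is multiplicative log-normal with
    coefficient of variation ``animal_cv`` applied to coverage, width
    scale, speeds and HRF amplitude/latency.
    """

    n_young: int = 6
    n_aged: int = 7
    grid_shape: tuple[int, int] = (330, 330)
    pixel_size_um: float = 2.0
    coverage_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "cortex": 0.20,
            "hippocampus": 0.16,
            "white_matter": 0.12,
        }
    )
    width_median_um: float = 14.0
    width_sigma: float = 0.35
    width_max_um: float = 50.0
    velocity_mm_s: dict[str, float] = field(
        default_factory=lambda: {
            "cortex": 10.0,
            "hippocampus": 8.0,
            "white_matter": 6.0,
        }
    )
    velocity_cv: float = 0.15
    hrf: HrfParams = HrfParams()
    schedule: StimSchedule = StimSchedule()
    arteriole_fraction: float = 0.6
    animal_cv: float = 0.05
    aged_effects: AgedEffects = AgedEffects()
    vessel_length_um: tuple[float, float] = (80.0, 180.0)

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_aged < 2:
            raise ValueError("need at least 2 animals per group")


@dataclass
class AnimalPhantom:
    """One synthetic animal: scene, rendered exports, regions, NVC trace
    and the ground-truth record used by recovery tests."""

    animal_id: str
    group: str
    scene: PhantomScene
    regions: RegionSet
    density: IntensityMap
    speed: IntensityMap
    directional: IntensityMap
    trace: NvcTrace
    truth: dict


@dataclass
class Cohort:
    params: CohortParams
    seed: int
    animals: list[AnimalPhantom]


def _jitter(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative log-normal jitter with coefficient of
    variation ~cv (exact mean 1)."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return float(rng.lognormal(-(sigma**2) / 2.0, sigma))


def _sample_region_vessels(
    rng: np.random.Generator,
    rect: tuple[int, int, int, int],
    region: str,
    params: CohortParams,
    coverage_target: float,
    width_scale: float,
    velocity_mean: float,
    arteriole_fraction: float,
) -> list[VesselSpec]:
    """Fill one rectangular region with vessels until the analytic capsule
    area reaches the target coverage fraction of the region area.

    Cortical vessels run near-vertically (penetrating arterioles and
    ascending venules); deeper regions get isotropic orientations.  The
    arteriole (descending) fraction is met by area quota, which keeps the
    realized arteriole/venule split close to its target in every animal.
    """
    px = params.pixel_size_um
    r0, r1, c0, c1 = rect
    y_lo, y_hi = r0 * px, r1 * px
    x_lo, x_hi = c0 * px, c1 * px
    region_area = (y_hi - y_lo) * (x_hi - x_lo)
    target_area = coverage_target * region_area

    vessels: list[VesselSpec] = []
    placed_area = 0.0
    arteriole_area = 0.0
    attempts = 0
    while placed_area < target_area and attempts < 10_000:
        attempts += 1
        width = float(
            np.clip(
                rng.lognormal(np.log(params.width_median_um), params.width_sigma)
                * width_scale,
                3.0,
                params.width_max_um,
            )
        )
        length = float(rng.uniform(*params.vessel_length_um))
        if region == "cortex":
            angle = np.pi / 2 + rng.normal(0.0, np.deg2rad(10.0))
        else:
            angle = rng.uniform(0.0, np.pi)
        dy = np.sin(angle) * length / 2.0
        dx = np.cos(angle) * length / 2.0
        margin = width / 2.0 + px
        # shrink vessels that cannot fit the region at this orientation
        avail_y = (y_hi - y_lo) / 2.0 - margin
        avail_x = (x_hi - x_lo) / 2.0 - margin
        if avail_y <= px or avail_x <= px:
            continue
        scale = min(1.0, avail_y / max(abs(dy), 1e-9),
                    avail_x / max(abs(dx), 1e-9))
        if length * scale < 6.0 * px:
            continue  # too short to be a meaningful segment; resample
        dy *= scale
        dx *= scale
        cy_lo = y_lo + abs(dy) + margin
        cy_hi = y_hi - abs(dy) - margin
        cx_lo = x_lo + abs(dx) + margin
        cx_hi = x_hi - abs(dx) - margin
        if cy_lo >= cy_hi or cx_lo >= cx_hi:
            continue
        cy = rng.uniform(cy_lo, cy_hi)
        cx = rng.uniform(cx_lo, cx_hi)
        velocity = float(
            np.clip(
                rng.normal(velocity_mean, params.velocity_cv * velocity_mean),
                0.5,
                100.0,
            )
        )
        # assign direction by area quota toward the arteriole fraction
        prospective = placed_area + 1.0  # avoid 0/0 on the first vessel
        if arteriole_area / prospective < arteriole_fraction:
            direction = DESCENDING
            arteriole_area += length * width
        else:
            direction = ASCENDING
        spec = VesselSpec(
            endpoints=((cy - dy, cx - dx), (cy + dy, cx + dx)),
            width_um=width,
            velocity_mm_s=velocity,
            axial_direction=direction,
        )
        vessels.append(spec)
        placed_area += spec.analytic_area_um2
    if not vessels:
        raise RuntimeError(f"could not place any vessel in region {region!r}")
    return vessels


def _simulate_animal(
    rng: np.random.Generator,
    animal_id: str,
    group: str,
    params: CohortParams,
    regions: RegionSet,
    layout: dict[str, tuple[int, int, int, int]],
) -> AnimalPhantom:
    eff = params.aged_effects if group == "aged" else AgedEffects.none()
    vel_mult = {
        "cortex": eff.velocity_cortex,
        "hippocampus": eff.velocity_hippocampus,
        "white_matter": eff.velocity_white_matter,
    }
    cov_jit = _jitter(rng, params.animal_cv)
    width_jit = _jitter(rng, params.animal_cv)
    vel_jit = _jitter(rng, params.animal_cv)
    art_frac = float(
        np.clip(params.arteriole_fraction * eff.arteriole_fraction, 0.05, 0.95)
    )

    vessels: list[VesselSpec] = []
    truth_regions: dict[str, dict] = {}
    for region, rect in layout.items():
        cov = params.coverage_fraction[region] * eff.coverage * cov_jit
        vmean = params.velocity_mm_s[region] * vel_mult[region] * vel_jit
        specs = _sample_region_vessels(
            rng,
            rect,
            region,
            params,
            coverage_target=cov,
            width_scale=eff.width * width_jit,
            velocity_mean=vmean,
            arteriole_fraction=art_frac,
        )
        vessels.extend(specs)
        areas = np.array([s.analytic_area_um2 for s in specs])
        widths = np.array([s.width_um for s in specs])
        vels = np.array([s.velocity_mm_s for s in specs])
        truth_regions[region] = {
            "target_coverage_fraction": cov,
            "n_vessels": len(specs),
            "mean_width_um": float(np.average(widths, weights=areas)),
            "mean_velocity_mm_s": float(np.average(vels, weights=areas)),
        }

    scene = make_scene(
        vessels, params.grid_shape, params.pixel_size_um, seed=0
    )
    hrf = params.hrf
    hrf = replace(
        hrf,
        amplitude_pct=hrf.amplitude_pct * eff.hrf_amplitude * _jitter(rng, params.animal_cv),
        latency_s=hrf.latency_s * eff.hrf_latency * _jitter(rng, params.animal_cv),
    )
    trace = simulate_nvc_trace(
        hrf, params.schedule, seed=rng, animal_id=animal_id, group=group
    )
    return AnimalPhantom(
        animal_id=animal_id,
        group=group,
        scene=scene,
        regions=regions,
        density=render_density_map(scene),
        speed=render_speed_map(scene),
        directional=render_directional_map(scene),
        trace=trace,
        truth={
            "regions": truth_regions,
            "arteriole_fraction": art_frac,
            "hrf_amplitude_pct": hrf.amplitude_pct,
            "hrf_latency_s": hrf.latency_s,
        },
    )


def simulate_cohort(params: CohortParams = CohortParams(), seed: int = 0) -> Cohort:
    """Generate the full young/aged phantom cohort.

    The master seed spawns one independent stream per animal (young
    first, then aged), so adding animals never perturbs earlier ones.
    """
    layout = horizontal_bands(params.grid_shape)
    regions = make_region_set(
        params.grid_shape, layout, pixel_size_um=params.pixel_size_um
    )
    streams = np.random.SeedSequence(seed).spawn(params.n_young + params.n_aged)
    animals: list[AnimalPhantom] = []
    idx = 0
    for group, n in (("young", params.n_young), ("aged", params.n_aged)):
        for i in range(n):
            rng = np.random.default_rng(streams[idx])
            animals.append(
                _simulate_animal(rng, f"{group}_{i:02d}", group, params, regions, layout)
            )
            idx += 1
    return Cohort(params=params, seed=seed, animals=animals)
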