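"""Synthetic whole-body-like PET phantoms with ground truth and observers.

The generator emulates the measurement situation of a two-reader metabolic
tumour volume (MTV) study in lymphoma: SUV volumes containing focal lesions
and infiltrative lesion clusters on a low uptake background, a liver region
providing reference statistics, two observers who place bounding boxes
around lesions (differing by margin jitter and by split-vs-merge decisions
on infiltrative clusters), and survival outcomes whose hazard depends on the
true tumour burden plus binary clinical covariates.

Default voxel geometry follows a clinical whole-body FDG-PET acquisition:
5.3 mm in-plane pixels, 2 mm plane spacing, and a reconstructed transverse
resolution of 4.4 mm FWHM modelled as an isotropic Gaussian point-spread
function.  Noise is additive Gaussian on the post-PSF volume, clipped at
zero — a desk-scale stand-in for reconstructed PET noise that is sufficient
to exercise threshold behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import LesionBox, SUVVolume

__all__ = [
    "SphereLesion",
    "LiverSpec",
    "PhantomConfig",
    "PhantomTruth",
    "ObserverModel",
    "SurvivalConfig",
    "CohortRecord",
    "PatientBundle",
    "generate_phantom",
    "place_observer_boxes",
    "random_phantom_config",
    "simulate_survival_records",
    "simulate_cohort",
    "sphere_volume_cm3",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def sphere_volume_cm3(radius_mm: float) -> float:
    """Analytic volume of a sphere, in cm^3."""
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


@dataclass(frozen=True)
class SphereLesion:
    """A spherical uptake region. ``cluster_id`` groups members of an
    infiltrative cluster; isolated lesions use ``cluster_id = None``."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake: float
    cluster_id: int | None = None

    @property
    def true_volume_cm3(self) -> float:
        return sphere_volume_cm3(self.radius_mm)


@dataclass(frozen=True)
class LiverSpec:
    """Spherical liver reference region (mean uptake plus voxel texture)."""

    center_mm: tuple[float, float, float] = (90.0, 90.0, 64.0)
    radius_mm: float = 25.0
    mean_suv: float = 2.2
    sd_suv: float = 0.2


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (168, 168, 64)
    spacing: tuple[float, float, float] = (5.3, 5.3, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background: float = 1.0
    psf_fwhm_mm: float = 4.4
    noise_sd: float = 0.0
    lesions: list[SphereLesion] = field(default_factory=list)
    liver: LiverSpec | None = field(default_factory=LiverSpec)
    spleen_state: str = "absent"  # absent | focal | diffuse
    spleen_ratio_to_liver: float = 1.0
    marrow_state: str = "absent"  # absent | focal | diffuse


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom, in physical units."""

    lesions: list[SphereLesion]
    liver: LiverSpec | None
    background: float
    spleen_state: str
    spleen_ratio_to_liver: float
    marrow_state: str
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    psf_fwhm_mm: float

    @property
    def lesion_volumes_cm3(self) -> list[float]:
        return [les.true_volume_cm3 for les in self.lesions]

    @property
    def total_volume_cm3(self) -> float:
        return float(sum(self.lesion_volumes_cm3))

    def tight_box(self, lesion: SphereLesion, lesion_id: int = -1) -> LesionBox:
        """Bounding box of the lesion's suprathreshold support.

        The support is the sphere dilated by the PSF FWHM, which covers the
        blur tail that threshold methods can pick up.
        """
        margin = lesion.radius_mm + self.psf_fwhm_mm
        low, high = [], []
        for ax in range(3):
            c = lesion.center_mm[ax] - self.origin[ax]
            lo = int(math.floor((c - margin) / self.spacing[ax]))
            hi = int(math.ceil((c + margin) / self.spacing[ax])) + 1
            low.append(max(0, lo))
            high.append(min(self.shape[ax], hi))
        return LesionBox(low=tuple(low), high=tuple(high), lesion_id=lesion_id)

    def liver_bbox(self) -> LesionBox | None:
        if self.liver is None:
            return None
        low, high = [], []
        for ax in range(3):
            c = self.liver.center_mm[ax] - self.origin[ax]
            lo = int(math.floor((c - self.liver.radius_mm) / self.spacing[ax]))
            hi = int(math.ceil((c + self.liver.radius_mm) / self.spacing[ax])) + 1
            low.append(max(0, lo))
            high.append(min(self.shape[ax], hi))
        return LesionBox(low=tuple(low), high=tuple(high), lesion_id=-2, label="liver")


def _sphere_mask(shape, spacing, origin, center_mm, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside the sphere."""
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    dx = (axes[0] - center_mm[0])[:, None, None] ** 2
    dy = (axes[1] - center_mm[1])[None, :, None] ** 2
    dz = (axes[2] - center_mm[2])[None, None, :] ** 2
    return dx + dy + dz <= radius_mm**2


def generate_phantom(config: PhantomConfig, seed: int) -> tuple[SUVVolume, PhantomTruth]:
    """Build a seeded synthetic SUV volume and its ground truth.

    The noiseless field is the voxel-centre indicator composition of all
    uptake regions over the uniform background (overlapping regions take the
    maximum uptake), convolved with an isotropic Gaussian PSF of the stated
    FWHM.  Optional additive Gaussian noise is applied afterwards and the
    result clipped at zero.  Identical ``(config, seed)`` give bit-identical
    volumes.
    """
    if config.psf_fwhm_mm < 0:
        raise ValueError(f"PSF FWHM must be >= 0, got {config.psf_fwhm_mm}")
    if config.noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    shape, spacing, origin = config.shape, config.spacing, config.origin
    extent = [origin[a] + spacing[a] * (shape[a] - 1) for a in range(3)]
    for les in config.lesions:
        if les.uptake <= config.background:
            raise ValueError(f"lesion uptake {les.uptake} must exceed background {config.background}")
        for ax in range(3):
            if (les.center_mm[ax] - les.radius_mm < origin[ax]
                    or les.center_mm[ax] + les.radius_mm > extent[ax]):
                raise ValueError(f"lesion at {les.center_mm} (r={les.radius_mm} mm) lies outside the grid")
    rng = np.random.default_rng(seed)
    vol = np.full(shape, config.background, dtype=np.float64)

    liver_mask = None
    if config.liver is not None:
        for ax in range(3):
            c = config.liver.center_mm[ax]
            if c - config.liver.radius_mm < origin[ax] or c + config.liver.radius_mm > extent[ax]:
                raise ValueError(f"liver region at {config.liver.center_mm} "
                                 f"(r={config.liver.radius_mm} mm) lies outside the grid")
        liver_mask = _sphere_mask(shape, spacing, origin, config.liver.center_mm, config.liver.radius_mm)
        vol[liver_mask] = np.maximum(vol[liver_mask], config.liver.mean_suv)
        for les in config.lesions:
            d = math.dist(les.center_mm, config.liver.center_mm)
            if d < les.radius_mm + config.liver.radius_mm:
                raise ValueError("lesion overlaps the liver reference region")

    for les in config.lesions:
        mask = _sphere_mask(shape, spacing, origin, les.center_mm, les.radius_mm)
        vol[mask] = np.maximum(vol[mask], les.uptake)

    if config.psf_fwhm_mm > 0:
        sigma_vox = [config.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
        vol = gaussian_filter(vol, sigma=sigma_vox, mode="nearest")

    if config.liver is not None and config.liver.sd_suv > 0:
        texture = rng.normal(0.0, config.liver.sd_suv, size=int(liver_mask.sum()))
        vol[liver_mask] += texture
    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=shape)
    np.clip(vol, 0.0, None, out=vol)

    truth = PhantomTruth(
        lesions=list(config.lesions),
        liver=config.liver,
        background=config.background,
        spleen_state=config.spleen_state,
        spleen_ratio_to_liver=config.spleen_ratio_to_liver,
        marrow_state=config.marrow_state,
        shape=shape,
        spacing=spacing,
        origin=origin,
        psf_fwhm_mm=config.psf_fwhm_mm,
    )
    return SUVVolume(values=vol, spacing=spacing, origin=origin), truth


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic model of one observer's box-placement behaviour.

    ``box_margin_jitter`` is the SD (in voxels) of the non-negative outward
    margin added independently to each box face; ``split_merge_probability``
    is the probability that an infiltrative cluster is delineated as one
    merged box rather than one box per member lesion.
    """

    box_margin_jitter: float = 0.0
    split_merge_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_margin_jitter < 0:
            raise ValueError("box margin jitter SD must be >= 0")
        if not 0.0 <= self.split_merge_probability <= 1.0:
            raise ValueError("split/merge probability must be in [0, 1]")


def _trim_against(box: LesionBox, forbidden: LesionBox, core: LesionBox) -> LesionBox:
    """Pull box faces back to avoid ``forbidden`` where the core allows it."""
    low, high = list(box.low), list(box.high)
    overlaps = all(low[a] < forbidden.high[a] and high[a] > forbidden.low[a] for a in range(3))
    if not overlaps:
        return box
    for ax in range(3):
        if high[ax] > forbidden.low[ax] >= core.high[ax]:
            high[ax] = forbidden.low[ax]
        if low[ax] < forbidden.high[ax] <= core.low[ax]:
            low[ax] = forbidden.high[ax]
    return LesionBox(low=tuple(low), high=tuple(high), lesion_id=box.lesion_id, label=box.label)


def place_observer_boxes(truth: PhantomTruth, model: ObserverModel) -> list[LesionBox]:
    """Simulate one observer's region-of-interest boxes around each lesion.

    With zero jitter and zero split/merge probability the returned boxes are
    exactly the tight ground-truth boxes.  Jitter widens boxes outward only,
    so every box keeps containing its lesion's suprathreshold support; boxes
    are clipped to the grid and trimmed so they never include the liver
    reference region.
    """
    rng = np.random.default_rng(model.seed)
    tight = [truth.tight_box(les, lesion_id=i) for i, les in enumerate(truth.lesions)]
    cluster_ids = sorted({les.cluster_id for les in truth.lesions if les.cluster_id is not None})

    units: list[LesionBox] = []  # pre-jitter boxes
    for i, les in enumerate(truth.lesions):
        if les.cluster_id is None:
            units.append(tight[i])
    for cid in cluster_ids:
        idxs = [i for i, les in enumerate(truth.lesions) if les.cluster_id == cid]
        members = [tight[i] for i in idxs]
        merged = rng.random() < model.split_merge_probability
        if merged or len(members) == 1:
            box = members[0]
            for b in members[1:]:
                box = b.union(box)
            units.append(LesionBox(low=box.low, high=box.high,
                                   lesion_id=box.lesion_id, label=f"cluster{cid}:merged"))
        else:
            # split: per-member tight boxes, clipped at the midplane between
            # neighbouring member centres so no box invades a neighbour's
            # hot core (the reading-room way of carving an infiltrated region)
            centers = np.array([truth.lesions[i].center_mm for i in idxs])
            axis = int(np.argmax(np.ptp(centers, axis=0)))
            order = np.argsort(centers[:, axis])
            cuts = []
            for a, b in zip(order[:-1], order[1:]):
                mid_mm = 0.5 * (centers[a, axis] + centers[b, axis])
                cuts.append(int(round((mid_mm - truth.origin[axis]) / truth.spacing[axis])))
            for rank, k in enumerate(order):
                box = members[k]
                low, high = list(box.low), list(box.high)
                if rank > 0:
                    low[axis] = max(low[axis], cuts[rank - 1])
                if rank < len(order) - 1:
                    high[axis] = min(high[axis], cuts[rank])
                if low[axis] >= high[axis]:  # degenerate clip: keep the tight box
                    low, high = list(box.low), list(box.high)
                units.append(LesionBox(low=tuple(low), high=tuple(high),
                                       lesion_id=box.lesion_id,
                                       label=f"cluster{cid}:split{rank}"))

    liver_box = truth.liver_bbox()
    out: list[LesionBox] = []
    for box in units:
        low, high = list(box.low), list(box.high)
        if model.box_margin_jitter > 0:
            margins = np.maximum(0, np.round(
                rng.normal(0.0, model.box_margin_jitter, size=6))).astype(int)
            for ax in range(3):
                low[ax] = max(0, low[ax] - margins[ax])
                high[ax] = min(truth.shape[ax], high[ax] + margins[3 + ax])
        if any(low[a] >= truth.shape[a] or high[a] <= 0 for a in range(3)):
            raise ValueError(f"observer box for lesion {box.lesion_id} fell outside the grid")
        jittered = LesionBox(low=tuple(low), high=tuple(high),
                             lesion_id=box.lesion_id, label=box.label)
        if liver_box is not None:
            jittered = _trim_against(jittered, liver_box, core=box)
        out.append(jittered)
    return out


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class SurvivalConfig:
    """Proportional-hazards outcome generator.

    Defaults restate the clinical world the analysis targets: exponential
    baseline hazard, log-hazard coefficients on the high-burden group
    (0.84 -> HR 2.31), an adverse IPI group (0.59) and chemotherapy group
    (1.11), covariate prevalences of 58.2% (IPI 3-5) and 72% (CHOP family),
    and uniform administrative censoring reproducing a several-year
    follow-up; the analysis additionally censors at 5 years downstream.
    ``volume_cutoff_cm3 = None`` splits at the cohort median true volume.
    """

    baseline_hazard: float = 0.10  # events / year in the reference group
    coef_volume: float = 0.84
    coef_ipi: float = 0.59
    coef_ct: float = 1.11
    p_ipi_high: float = 0.582
    p_ct_chop: float = 0.72
    volume_cutoff_cm3: float | None = None
    censor_low_years: float = 3.0
    censor_high_years: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.censor_high_years < self.censor_low_years or self.censor_low_years < 0:
            raise ValueError("invalid censoring window")


@dataclass(frozen=True)
class CohortRecord:
    patient_id: int
    true_total_volume_cm3: float
    time_years: float
    event: int
    ipi_high: int
    ct_chop: int
    volume_group_high: int

    def __post_init__(self) -> None:
        if self.time_years <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class PatientBundle:
    record: CohortRecord
    volume: SUVVolume
    truth: PhantomTruth
    boxes: dict[int, list[LesionBox]]  # observer id (1, 2) -> boxes


def random_phantom_config(rng: np.random.Generator,
                          base: PhantomConfig | None = None) -> PhantomConfig:
    """Draw one patient's lesion layout on a compact per-patient grid.

    Patients carry 1-3 isolated spherical lesions (radius 8-22 mm) plus 1-2
    infiltrative clusters of 2-4 overlapping spheres with unequal uptakes
    (radius 10-18 mm) — the disease presentations that drive observer
    split/merge disagreement.  Uptakes are uniform on SUV 4-12 over a
    background of 1.0, with the liver reference sphere in a fixed corner.
    """
    if base is None:
        base = PhantomConfig(shape=(64, 64, 64), spacing=(5.3, 5.3, 2.0),
                             noise_sd=0.15,
                             liver=LiverSpec(center_mm=(280.0, 280.0, 64.0),
                                             radius_mm=22.0, mean_suv=2.2, sd_suv=0.2))
    shape, spacing, origin = base.shape, base.spacing, base.origin
    extent = [origin[a] + spacing[a] * (shape[a] - 1) for a in range(3)]
    liver = base.liver

    placed: list[SphereLesion] = []

    def fits(center, radius) -> bool:
        for ax in range(3):
            if center[ax] - radius < origin[ax] + spacing[ax] or center[ax] + radius > extent[ax] - spacing[ax]:
                return False
        if liver is not None and math.dist(center, liver.center_mm) < radius + liver.radius_mm + 8.0:
            return False
        for other in placed:
            min_gap = 0.0 if other.cluster_id is not None else 6.0
            if math.dist(center, other.center_mm) < radius + other.radius_mm + min_gap:
                return False
        return True

    def sample_center(radius: float) -> tuple[float, float, float] | None:
        for _ in range(200):
            c = tuple(rng.uniform(origin[a] + radius + spacing[a],
                                  extent[a] - radius - spacing[a]) for a in range(3))
            if fits(c, radius):
                return c
        return None

    n_isolated = int(rng.integers(1, 4))
    for _ in range(n_isolated):
        r = float(rng.uniform(8.0, 22.0))
        c = sample_center(r)
        if c is None:
            continue
        placed.append(SphereLesion(center_mm=c, radius_mm=r,
                                   uptake=float(rng.uniform(4.0, 12.0))))

    n_clusters = int(rng.integers(1, 3))
    cid = 0
    for _ in range(n_clusters):
        r0 = float(rng.uniform(10.0, 18.0))
        c0 = sample_center(r0)
        if c0 is None:
            continue
        members = [SphereLesion(center_mm=c0, radius_mm=r0,
                                uptake=float(rng.uniform(6.0, 12.0)), cluster_id=cid)]
        n_members = int(rng.integers(2, 5))
        for _ in range(n_members - 1):
            r = float(rng.uniform(10.0, 18.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchor = members[-1]
            # abutting nodes: centres just under the sum of radii apart, so
            # each member keeps its own hot core
            gap = float(rng.uniform(0.95, 1.10))
            c = tuple(anchor.center_mm[a] + gap * (anchor.radius_mm + r) * direction[a]
                      for a in range(3))
            if not fits(c, r):
                continue
            # the dimmer members are what the 41% rule mis-sizes when merged
            members.append(SphereLesion(center_mm=c, radius_mm=r,
                                        uptake=float(rng.uniform(3.0, 8.0)), cluster_id=cid))
        placed.extend(members)
        cid += 1

    if not placed:  # extremely unlikely; guarantee at least one lesion
        placed.append(SphereLesion(center_mm=tuple((origin[a] + extent[a]) / 2 for a in range(3)),
                                   radius_mm=15.0, uptake=8.0))
    return replace(base, lesions=placed)


def simulate_survival_records(true_volumes: np.ndarray, config: SurvivalConfig,
                              seed: int) -> list[CohortRecord]:
    """Draw outcome records from the proportional-hazards model."""
    true_volumes = np.asarray(true_volumes, dtype=float)
    n = true_volumes.size
    if n <= 0:
        raise ValueError("cohort size must be > 0")
    rng = np.random.default_rng(seed)
    cutoff = (float(np.median(true_volumes)) if config.volume_cutoff_cm3 is None
              else config.volume_cutoff_cm3)
    high = (true_volumes >= cutoff).astype(int)
    ipi = (rng.random(n) < config.p_ipi_high).astype(int)
    ct = (rng.random(n) < config.p_ct_chop).astype(int)
    lp = config.coef_volume * high + config.coef_ipi * ipi + config.coef_ct * ct
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_high_years == config.censor_low_years:
        t_cens = np.full(n, config.censor_high_years)
    else:
        t_cens = rng.uniform(config.censor_low_years, config.censor_high_years, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # times must stay strictly positive
    return [CohortRecord(patient_id=i, true_total_volume_cm3=float(true_volumes[i]),
                         time_years=float(time[i]), event=int(event[i]),
                         ipi_high=int(ipi[i]), ct_chop=int(ct[i]),
                         volume_group_high=int(high[i]))
            for i in range(n)]


def simulate_cohort(n: int,
                    observer_models: tuple[ObserverModel, ObserverModel],
                    survival_config: SurvivalConfig | None = None,
                    phantom_base: PhantomConfig | None = None,
                    seed: int = 0):
    """Yield ``PatientBundle`` objects for a simulated two-reader cohort.

    A generator is used so that per-patient volumes can be consumed and
    discarded; per-patient seeds are spawned deterministically from the
    master seed, so any patient can be regenerated independently.
    """
    if n <= 0:
        raise ValueError("cohort size must be > 0")
    if survival_config is None:
        survival_config = SurvivalConfig()
    master = np.random.SeedSequence(seed)
    layout_seed, outcome_seed, *patient_seeds = master.spawn(2 + n)

    layout_rng = np.random.default_rng(layout_seed)
    configs = [random_phantom_config(layout_rng, base=phantom_base) for _ in range(n)]
    true_volumes = np.array([sum(l.true_volume_cm3 for l in cfg.lesions) for cfg in configs])
    records = simulate_survival_records(
        true_volumes, survival_config,
        seed=int(outcome_seed.generate_state(1)[0] % (2**31)))

    for i in range(n):
        sub = patient_seeds[i].generate_state(3) % (2**31)
        volume, truth = generate_phantom(configs[i], seed=int(sub[0]))
        boxes = {}
        for obs_id, model in zip((1, 2), observer_models):
            obs_model = replace(model, seed=int(sub[obs_id]))
            boxes[obs_id] = place_observer_boxes(truth, obs_model)
        yield PatientBundle(record=records[i], volume=volume, truth=truth, boxes=boxes)
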