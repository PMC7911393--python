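"""Eight lesion-delineation methods on an SUV volume restricted to a box.

Three absolute-threshold methods (fixed SUV 2.5, liver SUVmax, PERCIST
level), one relative method (41% of the box SUVmax) and four adaptive
methods (Nestle, Black, Daisne-type iterative signal-to-background, and a
geometric sphere-fitting method) produce binary lesion masks whose voxel
counts convert to metabolic volumes in cm^3.

Conventions: thresholds are inclusive (``SUV >= T``) everywhere; no
connected-component filtering is applied — the mask is every suprathreshold
voxel inside the observer's box, which is exactly what makes the relative
method sensitive to the box contents while the absolute methods are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.special import erf

from .volume import LesionBox, SUVVolume

__all__ = [
    "METHOD_NAMES",
    "LiverStats",
    "MethodSpec",
    "LesionMask",
    "FittingResult",
    "compute_liver_stats",
    "percist_threshold",
    "apply_fixed_threshold",
    "apply_percent_max_threshold",
    "estimate_background",
    "segment_nestle",
    "segment_black",
    "segment_daisne",
    "calibrate_adaptive",
    "segment_fitting",
    "segment_lesion",
    "mask_volume_cm3",
    "blurred_sphere_profile",
]

METHOD_NAMES = ("suv2.5", "percent41", "liver_max", "percist",
                "daisne", "nestle", "fitting", "black")

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class LiverStats:
    """Automatic liver reference statistics over a fixed spherical ROI."""

    suv_mean: float
    suv_sd: float
    suv_max: float

    def __post_init__(self) -> None:
        if self.suv_sd < 0:
            raise ValueError("liver SD must be >= 0")
        if not (self.suv_max >= self.suv_mean >= 0):
            raise ValueError("liver stats must satisfy max >= mean >= 0")


@dataclass
class MethodSpec:
    """Name and tunable parameters of one delineation method."""

    name: str
    fraction: float = 0.41          # percent41: fraction of box SUVmax
    absolute_level: float = 2.5     # suv2.5: fixed SUV threshold
    beta: float = 0.15              # nestle: weighting of core + background
    high_fraction: float = 0.70     # nestle: core definition
    black_a: float = 0.307          # black: T = a*SUVmean + b
    black_b: float = 0.588
    daisne_m: float | None = None   # daisne: f = m/SBR + c (phantom-calibrated)
    daisne_c: float | None = None
    psf_fwhm_mm: float = 4.4        # fitting + default daisne calibration
    max_iter: int = 100
    tol: float = 0.0                # iterative methods stop on mask fixed point

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}; expected one of {METHOD_NAMES}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.absolute_level <= 0:
            raise ValueError("absolute level must be > 0")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")


@dataclass
class LesionMask:
    """Binary box-local mask with the threshold that was actually applied."""

    mask: np.ndarray                # bool, shape = box extents
    box: LesionBox
    method: str
    threshold: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = tuple(h - l for l, h in zip(self.box.low, self.box.high))
        if self.mask.shape != expected:
            raise ValueError(f"mask shape {self.mask.shape} does not match box {expected}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def mask_volume_cm3(mask: LesionMask | np.ndarray,
                    spacing: tuple[float, float, float]) -> float:
    """Volume of a binary mask: voxel count x voxel volume, in cm^3."""
    arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    dx, dy, dz = spacing
    return float(arr.sum()) * dx * dy * dz / 1000.0


# ---------------------------------------------------------------------------
# Liver statistics and absolute thresholds


def compute_liver_stats(volume: SUVVolume,
                        center_mm: tuple[float, float, float],
                        radius_mm: float) -> LiverStats:
    """Mean, sample SD (n-1 denominator) and max over the spherical liver ROI.

    The ROI is the set of voxels whose centres fall inside the sphere; it
    must lie fully inside the grid and contain at least two voxels.
    """
    for ax in range(3):
        lo = volume.origin[ax]
        hi = volume.origin[ax] + volume.spacing[ax] * (volume.shape[ax] - 1)
        if center_mm[ax] - radius_mm < lo or center_mm[ax] + radius_mm > hi:
            raise ValueError("liver ROI extends outside the grid")
    axes = [volume.voxel_centers_mm(a) for a in range(3)]
    d2 = ((axes[0] - center_mm[0])[:, None, None] ** 2
          + (axes[1] - center_mm[1])[None, :, None] ** 2
          + (axes[2] - center_mm[2])[None, None, :] ** 2)
    vals = volume.values[d2 <= radius_mm**2]
    if vals.size < 2:
        raise ValueError(f"liver ROI contains {vals.size} voxels; need >= 2")
    return LiverStats(suv_mean=float(vals.mean()),
                      suv_sd=float(vals.std(ddof=1)),
                      suv_max=float(vals.max()))


def percist_threshold(liver: LiverStats) -> float:
    """PERCIST lesion-inclusion level: 1.5 x liver SUVmean + 2 x liver SD."""
    return 1.5 * liver.suv_mean + 2.0 * liver.suv_sd


def _box_values(volume: SUVVolume, box: LesionBox) -> np.ndarray:
    box.validate_within(volume.shape)
    return volume.values[box.slices]


def apply_fixed_threshold(volume: SUVVolume, box: LesionBox,
                          threshold: float, method: str = "suv2.5") -> LesionMask:
    """All voxels in the box with ``SUV >= threshold``; may be empty."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    vals = _box_values(volume, box)
    return LesionMask(mask=vals >= threshold, box=box, method=method, threshold=threshold)


def apply_percent_max_threshold(volume: SUVVolume, box: LesionBox,
                                fraction: float = 0.41) -> LesionMask:
    """Threshold at ``fraction`` of the maximum SUV within the box.

    The threshold travels with the box contents: a hotter voxel entering the
    box raises it — the mechanism behind this method's observer sensitivity.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vals = _box_values(volume, box)
    vmax = float(vals.max())
    flags = {}
    if vmax == 0.0:
        flags["all_zero_box"] = True
        return LesionMask(mask=np.zeros_like(vals, dtype=bool), box=box,
                          method="percent41", threshold=0.0, flags=flags)
    t = fraction * vmax
    return LesionMask(mask=vals >= t, box=box, method="percent41", threshold=t, flags=flags)


def estimate_background(volume: SUVVolume, box: LesionBox, shell_width: int = 2,
                        exclusion: list[LesionBox] | None = None) -> float:
    """Mean SUV over a voxel shell around the box, excluding lesion boxes.

    The shell is the expanded box (by ``shell_width`` voxels per face,
    clipped to the grid) minus the box itself and minus any exclusion boxes.
    """
    if shell_width < 1:
        raise ValueError("shell width must be >= 1")
    box.validate_within(volume.shape)
    low = [max(0, box.low[a] - shell_width) for a in range(3)]
    high = [min(volume.shape[a], box.high[a] + shell_width) for a in range(3)]
    sel = np.zeros(volume.shape, dtype=bool)
    sel[tuple(slice(l, h) for l, h in zip(low, high))] = True
    sel[box.slices] = False
    for other in exclusion or []:
        other.validate_within(volume.shape)
        sel[other.slices] = False
    if not sel.any():
        raise ValueError("background shell is empty after exclusions")
    return float(volume.values[sel].mean())


# ---------------------------------------------------------------------------
# Adaptive methods


def segment_nestle(volume: SUVVolume, box: LesionBox, background: float,
                   beta: float = 0.15, high_fraction: float = 0.70) -> LesionMask:
    """Background-aware threshold ``T = beta * (I70 + background)``.

    ``I70`` is the mean SUV of the lesion core, defined as the box voxels at
    or above ``high_fraction`` of the box maximum.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    vals = _box_values(volume, box)
    vmax = float(vals.max())
    if vmax <= background:
        raise ValueError(
            f"box maximum {vmax:.3g} does not exceed background {background:.3g}: "
            "lesion indistinguishable")
    core = vals[vals >= high_fraction * vmax]
    i70 = float(core.mean())
    t = beta * (i70 + background)
    return LesionMask(mask=vals >= t, box=box, method="nestle", threshold=t,
                      flags={"i70": i70, "background": background})


def segment_black(volume: SUVVolume, box: LesionBox,
                  a: float = 0.307, b: float = 0.588,
                  max_iter: int = 100) -> LesionMask:
    """Iterative mean-based threshold ``T = a * SUVmean(mask) + b``.

    Starts from the 41%-of-max mask and iterates until the mask is a fixed
    point.  ``max_iter = 0`` returns the initial mask with a warning flag.
    """
    vals = _box_values(volume, box)
    init = apply_percent_max_threshold(volume, box, 0.41)
    mask, t = init.mask, init.threshold
    if max_iter == 0:
        return LesionMask(mask=mask, box=box, method="black", threshold=t,
                          flags={"warning": "max_iter 0: returned initial 41% mask",
                                 "iterations": 0})
    for it in range(1, max_iter + 1):
        if not mask.any():
            raise ValueError(f"threshold escaped lesion: empty mask at iteration {it} (T={t:.4g})")
        t_new = a * float(vals[mask].mean()) + b
        new_mask = vals >= t_new
        if np.array_equal(new_mask, mask):
            return LesionMask(mask=new_mask, box=box, method="black", threshold=t_new,
                              flags={"iterations": it})
        mask, t = new_mask, t_new
    raise RuntimeError(
        f"Black iteration did not converge in {max_iter} steps; last T={t:.4g}, "
        f"last mask size {int(mask.sum())}")


def segment_daisne(volume: SUVVolume, box: LesionBox, background: float,
                   m: float, c: float, max_iter: int = 100) -> LesionMask:
    """Iterative signal-to-background adaptive threshold.

    At each step the threshold fraction is ``f = m / SBR + c`` (clamped to
    (0, 1]) where ``SBR = SUVmean(mask) / background``; the mask is the box
    voxels at or above ``f x box max``.  The calibration constants ``(m, c)``
    come from :func:`calibrate_adaptive`.  In the vanishing-background limit
    (SBR -> inf) the rule reduces to fixed-fraction thresholding at ``c``.
    """
    if background <= 0:
        raise ValueError("background must be > 0")
    vals = _box_values(volume, box)
    vmax = float(vals.max())
    if vmax <= background:
        raise ValueError("box maximum does not exceed background: insufficient contrast")
    mask = apply_percent_max_threshold(volume, box, 0.41).mask
    prev_mask = None
    prev_t = float("nan")
    trace: list[tuple[float, float, int]] = []
    f = t = float("nan")
    for _ in range(max_iter):
        if not mask.any():
            raise RuntimeError(f"adaptive threshold escaped lesion; trace={trace}")
        sbr = float(vals[mask].mean()) / background
        if sbr <= 1.0:
            raise ValueError(f"insufficient contrast: SBR={sbr:.3g} <= 1")
        f = min(1.0, max(m / sbr + c, 1e-9))
        t = f * vmax
        new_mask = vals >= t
        trace.append((f, t, int(new_mask.sum())))
        if np.array_equal(new_mask, mask):
            return LesionMask(mask=new_mask, box=box, method="daisne", threshold=t,
                              flags={"fraction": f, "sbr": sbr, "iterations": len(trace)})
        if prev_mask is not None and np.array_equal(new_mask, prev_mask):
            # discrete 2-cycle: the fixed point lies between the two
            # thresholds; settle at their midpoint
            t_mid = 0.5 * (t + prev_t)
            return LesionMask(mask=vals >= t_mid, box=box, method="daisne",
                              threshold=t_mid,
                              flags={"fraction": t_mid / vmax, "sbr": sbr,
                                     "iterations": len(trace),
                                     "cycle_resolved": True})
        prev_mask, prev_t = mask, t
        mask = new_mask
    raise RuntimeError(f"Daisne iteration did not converge in {max_iter} steps; trace={trace}")


def calibrate_adaptive(sphere_diameters_mm: list[float], contrasts: list[float],
                       psf_fwhm_mm: float = 4.4,
                       spacing: tuple[float, float, float] = (5.3, 5.3, 2.0),
                       background: float = 1.0) -> tuple[float, float]:
    """Phantom calibration of the adaptive fraction-vs-SBR rule.

    For each (diameter, contrast) sphere phantom — noiseless, PSF-blurred —
    the threshold fraction recovering the true sphere volume is found by
    bisection on the fraction, and the fractions are regressed on 1/SBR to
    give ``(m, c)``.  Deterministic given the configuration.
    """
    from .phantom import PhantomConfig, SphereLesion, generate_phantom

    if len(sphere_diameters_mm) != len(contrasts):
        raise ValueError("need one contrast per sphere diameter")
    if len(sphere_diameters_mm) < 2:
        raise ValueError("need at least 2 calibration phantoms")

    fractions, inv_sbr = [], []
    for d, contrast in zip(sphere_diameters_mm, contrasts):
        r = d / 2.0
        margin = r + 3.0 * psf_fwhm_mm + 3.0 * max(spacing)
        shape = tuple(int(math.ceil(2 * margin / s)) + 1 for s in spacing)
        center = tuple(spacing[a] * (shape[a] - 1) / 2.0 for a in range(3))
        cfg = PhantomConfig(shape=shape, spacing=spacing, background=background,
                            psf_fwhm_mm=psf_fwhm_mm, noise_sd=0.0, liver=None,
                            lesions=[SphereLesion(center_mm=center, radius_mm=r,
                                                  uptake=contrast * background)])
        vol, truth = generate_phantom(cfg, seed=0)
        box = truth.tight_box(truth.lesions[0])
        vals = vol.values[box.slices]
        vmax = float(vals.max())
        vox_cm3 = vol.voxel_volume_cm3
        # target the voxelised sphere volume: "exact" recovery on a grid
        from .phantom import _sphere_mask

        true_cm3 = float(_sphere_mask(shape, spacing, (0.0, 0.0, 0.0),
                                      center, r).sum()) * vox_cm3

        lo, hi = 1e-6, 1.0
        f_mid = 0.5
        for _ in range(60):
            f_mid = 0.5 * (lo + hi)
            v = float((vals >= f_mid * vmax).sum()) * vox_cm3
            if abs(v - true_cm3) <= 0.5 * vox_cm3:
                break
            if v > true_cm3:
                lo = f_mid
            else:
                hi = f_mid
        mask = vals >= f_mid * vmax
        sbr = float(vals[mask].mean()) / background
        fractions.append(f_mid)
        inv_sbr.append(1.0 / sbr)

    if np.ptp(inv_sbr) < 1e-12:
        raise ValueError("degenerate calibration design: all phantoms share one SBR")
    m, c = np.polyfit(inv_sbr, fractions, 1)
    return float(m), float(c)


@lru_cache(maxsize=8)
def default_daisne_calibration(psf_fwhm_mm: float,
                               spacing: tuple[float, float, float]) -> tuple[float, float]:
    """Built-in four-phantom calibration spanning clinical lesion contrasts."""
    return calibrate_adaptive([20.0, 30.0, 40.0, 50.0], [3.0, 5.0, 8.0, 12.0],
                              psf_fwhm_mm=psf_fwhm_mm, spacing=spacing)


# ---------------------------------------------------------------------------
# Geometric fitting method


def blurred_sphere_profile(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Closed-form radial profile of a unit ball convolved with an isotropic
    Gaussian of width ``sigma`` (the chi-3 CDF form); smooth in all arguments."""
    r = np.asarray(r, dtype=float)
    if sigma <= 0:
        return (r <= radius).astype(float)
    s2 = sigma * math.sqrt(2.0)
    safe_r = np.maximum(r, 1e-9)
    out = 0.5 * (erf((radius - safe_r) / s2) + erf((radius + safe_r) / s2))
    out -= (sigma / (safe_r * math.sqrt(2.0 * math.pi))) * (
        np.exp(-((safe_r - radius) ** 2) / (2.0 * sigma**2))
        - np.exp(-((safe_r + radius) ** 2) / (2.0 * sigma**2)))
    center = (erf(radius / s2)
              - math.sqrt(2.0 / math.pi) * (radius / sigma)
              * math.exp(-(radius**2) / (2.0 * sigma**2)))
    return np.where(r < 1e-9, center, out)


@dataclass
class FittingResult:
    mask: LesionMask
    center_mm: tuple[float, float, float]
    diameter_mm: float
    uptake: float
    background: float
    volume_cm3: float
    residual_norm: float
    converged: bool


def segment_fitting(volume: SUVVolume, box: LesionBox, psf_fwhm_mm: float = 4.4,
                    background_init: float | None = None) -> FittingResult:
    """Fit a uniform sphere on a uniform background, blurred by the scanner
    PSF, to the box voxels; the MTV is the analytic fitted-sphere volume.

    The model sigma is floored at 0.35 x the smallest voxel spacing so the
    objective stays smooth (standing in for voxel partial-volume averaging);
    in the FWHM = 0 limit the fit therefore still recovers a sharp sphere to
    within a voxel shell.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("PSF FWHM must be >= 0")
    vals = _box_values(volume, box)
    if vals.size < 30:
        raise ValueError(f"box contains {vals.size} voxels; fitting needs >= 30")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin < 1e-6 * max(vmax, 1.0):
        raise ValueError("flat box: sphere parameters unidentifiable")

    spacing = volume.spacing
    sigma = max(psf_fwhm_mm * _FWHM_TO_SIGMA, 0.35 * min(spacing))
    axes = [volume.origin[a] + spacing[a] * np.arange(box.low[a], box.high[a])
            for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")

    bg0 = float(np.percentile(vals, 20)) if background_init is None else background_init
    core = vals >= vmin + 0.5 * (vmax - vmin)
    w = np.clip(vals - bg0, 0.0, None) * core
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("flat box: sphere parameters unidentifiable")
    c0 = (float((gx * w).sum() / wsum), float((gy * w).sum() / wsum),
          float((gz * w).sum() / wsum))
    vox_cm3 = volume.voxel_volume_cm3
    v0 = max(float(core.sum()) * vox_cm3, vox_cm3)
    r0 = (3.0 * v0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    def residuals(p):
        cx, cy, cz, radius, uptake, bg = p
        r = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2)
        model = bg + (uptake - bg) * blurred_sphere_profile(r, radius, sigma)
        return (model - vals).ravel()

    diag = math.sqrt(sum((a[-1] - a[0]) ** 2 for a in axes))
    lo_b = [axes[0][0] - 2 * spacing[0], axes[1][0] - 2 * spacing[1],
            axes[2][0] - 2 * spacing[2], 0.2 * min(spacing), 0.0, 0.0]
    hi_b = [axes[0][-1] + 2 * spacing[0], axes[1][-1] + 2 * spacing[1],
            axes[2][-1] + 2 * spacing[2], diag, 5.0 * vmax, vmax]
    p0 = [c0[0], c0[1], c0[2], r0, vmax, max(bg0, 1e-6)]
    p0 = np.clip(p0, lo_b, hi_b)
    fit = optimize.least_squares(residuals, p0, bounds=(lo_b, hi_b),
                                 xtol=1e-9, ftol=1e-9, max_nfev=600)
    if not fit.success:
        raise RuntimeError(f"sphere fit did not converge: {fit.message}")
    cx, cy, cz, radius, uptake, bg = fit.x
    if 2.0 * radius <= min(spacing):
        raise ValueError(f"sub-resolution lesion: fitted diameter {2 * radius:.3g} mm "
                         f"<= one voxel ({min(spacing):.3g} mm)")
    r_grid = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2)
    mask = LesionMask(mask=r_grid <= radius, box=box, method="fitting",
                      threshold=float("nan"),
                      flags={"fitted_sphere": True})
    return FittingResult(
        mask=mask, center_mm=(float(cx), float(cy), float(cz)),
        diameter_mm=float(2 * radius), uptake=float(uptake), background=float(bg),
        volume_cm3=4.0 / 3.0 * math.pi * float(radius) ** 3 / 1000.0,
        residual_norm=float(np.linalg.norm(fit.fun)), converged=bool(fit.success))


# ---------------------------------------------------------------------------
# Dispatch


def segment_lesion(volume: SUVVolume, box: LesionBox, spec: MethodSpec,
                   liver: LiverStats | None = None,
                   background: float | None = None,
                   exclusion: list[LesionBox] | None = None) -> LesionMask:
    """Apply one named method to one observer box.

    ``liver`` is required by the liver-max and PERCIST methods; adaptive
    methods estimate the local background from a shell around the box when
    ``background`` is not given.
    """
    name = spec.name
    if name == "suv2.5":
        return apply_fixed_threshold(volume, box, spec.absolute_level, method=name)
    if name == "percent41":
        return apply_percent_max_threshold(volume, box, spec.fraction)
    if name in ("liver_max", "percist"):
        if liver is None:
            raise ValueError(f"method {name!r} requires liver statistics")
        t = liver.suv_max if name == "liver_max" else percist_threshold(liver)
        return apply_fixed_threshold(volume, box, t, method=name)

    if background is None:
        background = estimate_background(volume, box, shell_width=2, exclusion=exclusion)
    if name == "nestle":
        return segment_nestle(volume, box, background, beta=spec.beta,
                              high_fraction=spec.high_fraction)
    if name == "black":
        return segment_black(volume, box, a=spec.black_a, b=spec.black_b,
                             max_iter=spec.max_iter)
    if name == "daisne":
        m, c = spec.daisne_m, spec.daisne_c
        if m is None or c is None:
            m, c = default_daisne_calibration(spec.psf_fwhm_mm, tuple(volume.spacing))
        return segment_daisne(volume, box, background, m=m, c=c, max_iter=spec.max_iter)
    if name == "fitting":
        result = segment_fitting(volume, box, psf_fwhm_mm=spec.psf_fwhm_mm,
                                 background_init=background)
        result.mask.flags["volume_cm3"] = result.volume_cm3
        return result.mask
    raise ValueError(f"unknown method {name!r}")  # pragma: no cover
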