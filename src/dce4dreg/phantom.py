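"""Synthetic 4D breast-DCE phantoms with known motion and perfusion.

Emulates the clinical acquisition protocol — six T1-weighted volumes
(unenhanced, +90 s after injection, then every 70 s), ~0.7 mm in-plane
spacing and 2 mm slices — on a desk-scale 64x64x16 grid so the full
registration/fitting pipeline runs in minutes.  Two ellipsoidal breast
regions carry a smooth random baseline texture and mild parenchymal
enhancement; a spherical lesion enhances according to the extended Tofts
model at configured ground-truth parameters.  Smooth inter-timepoint
patient motion is injected as a cubic B-spline free-form deformation
(identity at the unenhanced reference frame) and additive noise is applied
last, mimicking acquisition order: physiology -> motion -> noise.

Conventions: the unenhanced frame is rendered pre-injection (tissue
concentration 0); postcontrast frames carry signal
S = baseline * (1 + r * C_t(t)) with enhancement scale r per mM (linear
signal mode).  An optional spoiled-gradient-echo mode converts
concentration to signal through T1 shortening instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bspline import BSplineMotionModel
from .core import DceSeries
from .perfusion import Aif, ToftsParams, tofts_concentration

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom",
           "apply_motion", "add_noise", "PROTOCOL_TIMES_S"]

#: Clinical protocol: unenhanced, +90 s, then every 70 s (seconds).
PROTOCOL_TIMES_S = (0.0, 90.0, 160.0, 230.0, 300.0, 370.0)


@dataclass
class LesionSpec:
    """Spherical enhancing lesion: center (voxel coords), radius (mm), truth."""

    center: tuple = (45, 36, 8)
    radius_mm: float = 6.0
    ktrans: float = 0.103   # 1/min; realistic malignant-lesion magnitude
    ve: float = 0.3
    vp: float = 0.02


@dataclass
class TissueSpec:
    """Background region: ellipsoid (center/semi-axes in voxels) + physiology."""

    center: tuple
    semiaxes: tuple
    baseline: float = 100.0
    ktrans: float = 0.01    # mild parenchymal enhancement
    ve: float = 0.2
    vp: float = 0.005


def _default_breasts():
    return [TissueSpec(center=(17.0, 32.0, 8.0), semiaxes=(14.0, 26.0, 7.0)),
            TissueSpec(center=(47.0, 32.0, 8.0), semiaxes=(14.0, 26.0, 7.0))]


@dataclass
class PhantomConfig:
    """Full description of one synthetic case (defaults = study conditions)."""

    shape: tuple = (64, 64, 16)
    spacing: tuple = (0.7, 0.7, 2.0)
    times: tuple = PROTOCOL_TIMES_S
    lesion: LesionSpec = field(default_factory=LesionSpec)
    background_tissue: list = field(default_factory=_default_breasts)
    air_intensity: float = 2.0
    texture_amplitude: float = 0.25      # fractional baseline modulation
    texture_smoothing_vox: float = 2.5
    enhancement_per_mM: float = 5.0      # linear signal mode: dS/S0 per mM
    signal_mode: str = "linear"          # or "spgr"
    flip_angle_deg: float = 25.0         # spgr mode (protocol values)
    tr_ms: float = 7.5
    t1_baseline_ms: float = 1000.0
    relaxivity_per_s_mM: float = 4.5
    motion_mode: str = "bspline"         # none | rigid | bspline
    motion_amplitude_mm: float = 4.0     # max control-point displacement
    motion_control_spacing_mm: float = 22.0
    noise_sigma: float = 0.02            # relative to breast baseline signal
    noise_model: str = "gaussian"        # or "rician"
    seed: int = 0
    aif: Aif = field(default_factory=Aif)

    def __post_init__(self) -> None:
        ToftsParams(self.lesion.ktrans, self.lesion.ve, self.lesion.vp)
        if self.lesion.ve + self.lesion.vp > 1:
            raise ValueError("lesion ve + vp must not exceed 1")
        if self.motion_amplitude_mm < 0:
            raise ValueError("motion_amplitude_mm must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.motion_mode not in ("none", "rigid", "bspline"):
            raise ValueError(f"unknown motion_mode: {self.motion_mode}")
        if self.signal_mode not in ("linear", "spgr"):
            raise ValueError(f"unknown signal_mode: {self.signal_mode}")


@dataclass
class PhantomTruth:
    """Everything the generator knows and downstream validation needs."""

    lesion_mask: np.ndarray
    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    motion: BSplineMotionModel
    clean_series: DceSeries
    enhancement_scale: float = 1.0


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _sphere_mask(shape, spacing, center_vox, radius_mm) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    r2 = sum((((idx[a] - center_vox[a]) * spacing[a]) / radius_mm) ** 2
             for a in range(3))
    return r2 <= 1.0


def _signal_from_concentration(conc: np.ndarray, baseline: np.ndarray,
                               cfg: PhantomConfig) -> np.ndarray:
    if cfg.signal_mode == "linear":
        return baseline * (1.0 + cfg.enhancement_per_mM * conc)
    # spoiled gradient echo: T1 shortening by 1/T1 = 1/T10 + r1 * C
    alpha = np.deg2rad(cfg.flip_angle_deg)
    tr_s = cfg.tr_ms / 1000.0
    r10 = 1.0 / (cfg.t1_baseline_ms / 1000.0)
    r1 = r10 + cfg.relaxivity_per_s_mM * conc
    e1 = np.exp(-tr_s * r1)
    e10 = np.exp(-tr_s * r10)
    spgr = np.sin(alpha) * (1 - e1) / (1 - np.cos(alpha) * e1)
    spgr0 = np.sin(alpha) * (1 - e10) / (1 - np.cos(alpha) * e10)
    return baseline * spgr / spgr0


def _make_motion(cfg: PhantomConfig, rng: np.random.Generator
                 ) -> BSplineMotionModel:
    """Smooth random motion, identity at the reference (first) timepoint.

    Each control point gets a random direction whose temporal profile is a
    smooth cumulative walk; every postcontrast timepoint is rescaled so the
    peak displacement of its field equals ``motion_amplitude_mm``.
    """
    nt = len(cfg.times)
    model = BSplineMotionModel.for_domain(cfg.shape, cfg.spacing,
                                          cfg.motion_control_spacing_mm, nt)
    if cfg.motion_mode == "none" or cfg.motion_amplitude_mm == 0:
        return model
    if cfg.motion_mode == "rigid":
        # uniform translation per timepoint (partition of unity makes a
        # constant coefficient grid an exact translation)
        steps = rng.standard_normal((nt, 3))
        steps[0] = 0.0
        walk = np.cumsum(steps, axis=0)
        walk -= walk[0]
        scale = cfg.motion_amplitude_mm / max(np.abs(walk).max(), 1e-12)
        model.coefficients[:] = (walk * scale)[:, None, None, None, :]
        return model
    grid = model.grid_shape
    steps = rng.standard_normal((nt, *grid, 3))
    for t in range(nt):  # spatially smooth each increment
        for a in range(3):
            steps[t, ..., a] = ndimage.gaussian_filter(steps[t, ..., a], 1.0,
                                                       mode="nearest")
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    walk -= walk[:1]
    # each postcontrast timepoint is scaled so the maximum displacement of
    # its field over the image domain equals the amplitude (the walk
    # supplies the smooth spatial/directional pattern; the envelope is the
    # configured bound); by the partition of unity the field can never
    # exceed the largest control-point coefficient
    model.coefficients[:] = walk
    for t in range(1, nt):
        field = model.dense_displacement(cfg.shape, cfg.spacing, t)
        peak = np.linalg.norm(field, axis=-1).max()
        model.coefficients[t] *= cfg.motion_amplitude_mm / max(peak, 1e-12)
    return model


def apply_motion(series: DceSeries, motion: BSplineMotionModel,
                 order: int = 3) -> DceSeries:
    """Resample each volume through its timepoint's deformation (backward warp)."""
    if motion.n_timepoints != series.n_timepoints:
        raise ValueError("motion model and series timepoint counts differ")
    out = np.empty_like(np.asarray(series.voxels, dtype=float))
    for t in range(series.n_timepoints):
        if np.any(motion.coefficients[t]):
            out[..., t] = motion.warp_volume(
                np.ascontiguousarray(series.voxels[..., t], dtype=float),
                series.spacing, t, order=order)
        else:
            out[..., t] = series.voxels[..., t]
    return series.with_voxels(out)


def add_noise(series: DceSeries, sigma: float, seed: int,
              model: str = "gaussian") -> DceSeries:
    """Add seeded voxelwise noise (absolute intensity units)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series.with_voxels(np.array(series.voxels, copy=True))
    rng = np.random.default_rng(seed)
    vox = np.asarray(series.voxels, dtype=float)
    if model == "gaussian":
        out = vox + rng.normal(0.0, sigma, size=vox.shape)
    elif model == "rician":
        out = np.hypot(vox + rng.normal(0.0, sigma, size=vox.shape),
                       rng.normal(0.0, sigma, size=vox.shape))
    else:
        raise ValueError(f"unknown noise model: {model}")
    return series.with_voxels(out)


def generate_phantom(config: PhantomConfig | None = None, seed: int | None = None
                     ) -> tuple[DceSeries, PhantomTruth]:
    """Render one synthetic case: returns (corrupted series, ground truth).

    Deterministic: the same (config, seed) reproduces the output bit for
    bit.  With ``motion_mode="none"`` and ``noise_sigma=0`` the returned
    series equals the clean series exactly.
    """
    cfg = config if config is not None else PhantomConfig()
    if seed is not None:
        cfg = PhantomConfig(**{**cfg.__dict__, "seed": seed})
    shape = tuple(int(s) for s in cfg.shape)
    spacing = np.asarray(cfg.spacing, dtype=float)
    times = np.asarray(cfg.times, dtype=float)
    rng_texture = np.random.default_rng([cfg.seed, 11])
    rng_motion = np.random.default_rng([cfg.seed, 22])

    lesion_mask = _sphere_mask(shape, spacing, cfg.lesion.center,
                               cfg.lesion.radius_mm)
    if not lesion_mask.any():
        raise ValueError("lesion does not intersect the grid")
    if (lesion_mask[0].any() or lesion_mask[-1].any()
            or lesion_mask[:, 0].any() or lesion_mask[:, -1].any()
            or lesion_mask[:, :, 0].any() or lesion_mask[:, :, -1].any()):
        raise ValueError("lesion extends outside the grid")

    baseline = np.full(shape, cfg.air_intensity)
    ktrans_map = np.zeros(shape)
    ve_map = np.full(shape, 1.0)   # harmless filler where ktrans = 0
    vp_map = np.zeros(shape)
    tissue_mask = np.zeros(shape, dtype=bool)
    for tissue in cfg.background_tissue:
        m = _ellipsoid_mask(shape, tissue.center, tissue.semiaxes)
        tissue_mask |= m
        baseline[m] = tissue.baseline
        ktrans_map[m] = tissue.ktrans
        ve_map[m] = tissue.ve
        vp_map[m] = tissue.vp
    ktrans_map[lesion_mask] = cfg.lesion.ktrans
    ve_map[lesion_mask] = cfg.lesion.ve
    vp_map[lesion_mask] = cfg.lesion.vp

    # smooth multiplicative texture inside tissue (registration needs edges)
    noise = rng_texture.standard_normal(shape)
    texture = ndimage.gaussian_filter(noise, cfg.texture_smoothing_vox,
                                      mode="nearest")
    texture /= max(np.abs(texture).max(), 1e-12)
    baseline = baseline * np.where(tissue_mask,
                                   1.0 + cfg.texture_amplitude * texture, 1.0)

    # physiology: unique (ktrans, ve, vp) combinations share one curve
    nt = times.size
    clean = np.empty((*shape, nt))
    clean[..., 0] = baseline  # pre-injection reference frame
    combos = np.stack([ktrans_map.ravel(), ve_map.ravel(), vp_map.ravel()],
                      axis=1)
    uniq, inverse = np.unique(combos, axis=0, return_inverse=True)
    curves = np.zeros((uniq.shape[0], nt - 1))
    for u, (kt, ve, vp) in enumerate(uniq):
        if kt == 0 and vp == 0:
            continue
        params = ToftsParams(float(kt), float(ve), float(vp))
        curves[u] = tofts_concentration(times[1:], params, cfg.aif)
    conc = curves[inverse].reshape(*shape, nt - 1)
    for g in range(1, nt):
        clean[..., g] = _signal_from_concentration(conc[..., g - 1], baseline,
                                                   cfg)

    clean_series = DceSeries(voxels=clean, spacing=spacing.copy(),
                             times=times.copy())
    motion = _make_motion(cfg, rng_motion)
    series = apply_motion(clean_series, motion) if cfg.motion_mode != "none" \
        else clean_series.with_voxels(np.array(clean, copy=True))
    ref_baseline = max(t.baseline for t in cfg.background_tissue) \
        if cfg.background_tissue else 1.0
    if cfg.noise_sigma > 0:
        series = add_noise(series, cfg.noise_sigma * ref_baseline,
                           seed=int(np.random.default_rng([cfg.seed, 33])
                                    .integers(2 ** 31)),
                           model=cfg.noise_model)
    truth = PhantomTruth(lesion_mask=lesion_mask, ktrans_map=ktrans_map,
                         ve_map=ve_map, vp_map=vp_map, motion=motion,
                         clean_series=clean_series,
                         enhancement_scale=cfg.enhancement_per_mM
                         if cfg.signal_mode == "linear" else 1.0)
    return series, truth
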