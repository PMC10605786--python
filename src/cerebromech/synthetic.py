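"""Synthetic study inputs with known ground truth.

Four generators emulate the four data streams of the study:

* :func:`simulate_inflation` — a pressurized nonlinear-elastic artery at a
  built-in in-vivo axial stretch.  The circumferential material law is an
  exponential in the *normalized* mid-wall stretch,
  sigma_theta = c * (exp(b * (lam_n - 1)) - 1), with the zero-pressure
  reference at axial stretch lambda_z fixed by incompressibility plus
  mid-wall radius scaling 1/sqrt(lambda_z).  Defined this way, (c, b) is
  the exact ground truth for the downstream exponential fit on normalized
  stretch.  The axial force follows a phenomenological surface
  f_T = F0 + k_f * (lambda_z - lambda_z_star) * P whose pressure
  sensitivity vanishes exactly at the in vivo stretch lambda_z_star.
* :func:`generate_fiber_image` — a fiber-texture arterial cross-section
  with region-specific area fractions and a controllable fiber-free band
  at the media-adventitia interface.
* :func:`generate_polarization_stack` — the six-frame sinusoidal
  polarization intensity model I_k = a0*(1 + r*sin(2*(theta_k - phi))).
* :func:`generate_abundance_table` — log-normal protein abundance tables
  with group-specific collagen composition and optional spiked effects.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import line as _draw_line

from . import reference
from .fibergap import FiberImage, LayerAnnotation
from .mechanics import RingGeometry, InflationCycle, analyze_cycle
from .omics import AbundanceTable
from .qbrm import PolarizationStack, POLARIZER_ANGLES_DEG


class SyntheticError(ValueError):
    pass


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# extension-inflation simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParams:
    """Ground-truth material behaviour for the inflation simulator.

    c_theta/b_theta parameterize the circumferential exponential law (kPa
    scale / dimensionless rate); F0, k_f, lambda_z_star the axial force
    surface (mN, mN/mmHg per unit stretch, dimensionless); noise SDs are
    instrument-style additive noise on the recorded diameter and force.
    """

    c_theta_kPa: float = 30.0
    b_theta: float = 8.0
    F0_mN: float = 18.8
    k_f_mN_per_mmHg: float = 2.0
    lambda_z_star: float = 1.12
    diameter_noise_um: float = 0.0
    force_noise_mN: float = 0.0

    def __post_init__(self) -> None:
        if self.c_theta_kPa <= 0 or self.b_theta <= 0:
            raise SyntheticError("c_theta and b_theta must be positive")
        if not (1.0 <= self.lambda_z_star <= 1.3):
            raise SyntheticError("lambda_z_star must lie in [1.0, 1.3]")

    def axial_force(self, lambda_z: float, P_mmHg: float) -> float:
        return self.F0_mN + self.k_f_mN_per_mmHg * (lambda_z - self.lambda_z_star) * P_mmHg


DEFAULT_GEOMETRY = RingGeometry.from_radii(R_o_um=1000.0, R_i_um=830.0, unloaded_length_mm=10.0)


@dataclass
class SimulatedInflation:
    """Raw myograph-style recordings plus the generating ground truth."""

    geometry: RingGeometry
    material: MaterialParams
    lambda_z: float
    measurements: pd.DataFrame  # pressure_mmHg, outer_diameter_um, axial_force_mN
    true_outer_radii_um: np.ndarray  # noise-free r_o per pressure

    @property
    def stretched_length_mm(self) -> float:
        return self.lambda_z * self.geometry.unloaded_length_mm

    def analyze(self) -> InflationCycle:
        m = self.measurements
        return analyze_cycle(
            self.geometry,
            m["pressure_mmHg"].to_numpy(),
            m["outer_diameter_um"].to_numpy(),
            m["axial_force_mN"].to_numpy(),
            self.stretched_length_mm,
        )


def _zero_pressure_radius(geometry: RingGeometry, lambda_z: float) -> float:
    """Outer radius of the unloaded (P=0) state at axial stretch lambda_z.

    The mid-wall radius scales by 1/sqrt(lambda_z) (isochoric axial
    extension), tied to incompressibility for the wall volume.
    """
    A = geometry.R_o_um**2 - geometry.R_i_um**2
    target = (geometry.R_o_um + geometry.R_i_um) / math.sqrt(lambda_z)

    def g(r_o: float) -> float:
        return r_o + math.sqrt(r_o**2 - A / lambda_z) - target

    lo = math.sqrt(A / lambda_z) * (1 + 1e-12)
    hi = geometry.R_o_um * 2.0
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-15)


def simulate_inflation(
    geometry: RingGeometry = DEFAULT_GEOMETRY,
    material: MaterialParams = MaterialParams(),
    lambda_z: float | None = None,
    pressures_mmHg=None,
    seed=0,
) -> SimulatedInflation:
    """Simulate a depressurization limb of an extension-inflation test.

    For each pressure the deformed outer radius solves the thin-wall
    equilibrium P*r_i/(r_o - r_i) = sigma_theta(lam_n) by bracketed root
    finding, with r_i and lam_n tied to r_o through incompressibility.
    Additive Gaussian noise (per ``material``) lands on the recorded
    diameter and force only; the underlying state is exact.
    """
    rng = _rng(seed)
    if lambda_z is None:
        lambda_z = material.lambda_z_star
    if pressures_mmHg is None:
        pressures_mmHg = np.arange(80.0, -1.0, -10.0)  # 80 -> 0, 10 mmHg steps
    pressures = np.asarray(pressures_mmHg, dtype=float)

    A = geometry.R_o_um**2 - geometry.R_i_um**2
    r_o0 = _zero_pressure_radius(geometry, lambda_z)
    r_i0 = math.sqrt(r_o0**2 - A / lambda_z)
    mid0 = r_o0 + r_i0

    def sigma_mat_pa(lam_n: float) -> float:
        return material.c_theta_kPa * 1e3 * math.expm1(material.b_theta * (lam_n - 1.0))

    def residual(r_o: float, P_pa: float) -> float:
        r_i = math.sqrt(r_o**2 - A / lambda_z)
        lam_n = (r_o + r_i) / mid0
        return sigma_mat_pa(lam_n) * (r_o - r_i) - P_pa * r_i

    radii = np.empty(pressures.size)
    for i, P in enumerate(pressures):
        if P == 0:
            radii[i] = r_o0
            continue
        P_pa = P * 133.322
        lo, hi = r_o0, r_o0 * 1.5
        while residual(hi, P_pa) < 0:
            hi *= 1.5
            if hi > r_o0 * 50:
                raise SyntheticError(
                    f"no equilibrium radius found at {P} mmHg for the given material"
                )
        radii[i] = brentq(residual, lo, hi, args=(P_pa,), xtol=1e-12, rtol=1e-15)

    forces = np.array([material.axial_force(lambda_z, P) for P in pressures])
    d_noise = rng.normal(0.0, material.diameter_noise_um, pressures.size) if material.diameter_noise_um else 0.0
    f_noise = rng.normal(0.0, material.force_noise_mN, pressures.size) if material.force_noise_mN else 0.0
    meas = pd.DataFrame(
        {
            "pressure_mmHg": pressures,
            "outer_diameter_um": 2.0 * radii + d_noise,
            "axial_force_mN": forces + f_noise,
        }
    )
    return SimulatedInflation(
        geometry=geometry,
        material=material,
        lambda_z=float(lambda_z),
        measurements=meas,
        true_outer_radii_um=radii,
    )


def perturb_stresses(stress_kPa, frac: float, seed=0) -> np.ndarray:
    """Multiplicative Gaussian noise on stress observations (oracle for
    parameter-recovery studies)."""
    rng = _rng(seed)
    s = np.asarray(stress_kPa, dtype=float)
    return s * (1.0 + rng.normal(0.0, frac, s.shape))


# ---------------------------------------------------------------------------
# fiber-texture image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSceneParams:
    """Layout and texture of a synthetic elastic-fiber cross-section.

    Columns run intima | media | gap | adventitia along x (wall vertical).
    Target area fractions default to the study-scale media/adventitia
    fractions; the gap retains a sparse bridging fiber fraction.
    """

    width_px: int = 390
    height_px: int = 390
    pixel_size_um: float = 1.0
    intima_cols: tuple[int, int] = (0, 39)
    media_cols: tuple[int, int] = (39, 195)
    gap_width_um: float = 32.0
    intima_fraction: float = 0.35
    media_fraction: float = reference.MEDIA_AREA_FRACTION[0]
    adventitia_fraction: float = reference.ADVENTITIA_AREA_FRACTION[0]
    gap_fraction: float = 0.02
    fiber_len_px: tuple[int, int] = (20, 60)
    background_level: float = 10.0
    fiber_level: float = 200.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        for f in (self.intima_fraction, self.media_fraction, self.adventitia_fraction, self.gap_fraction):
            if not (0.0 <= f <= 1.0):
                raise SyntheticError("area fractions must lie in [0, 1]")
        gap_px = int(round(self.gap_width_um / self.pixel_size_um))
        if self.media_cols[1] + gap_px >= self.width_px:
            raise SyntheticError("gap does not fit between media and image edge")


@dataclass
class FiberScene:
    image: FiberImage
    mask: np.ndarray  # ground-truth fiber mask
    annotation: LayerAnnotation
    true_gap_um: float
    roi: tuple[int, int, int, int]


def _fill_region(
    mask: np.ndarray,
    cols: tuple[int, int],
    target: float,
    rng: np.random.Generator,
    len_range: tuple[int, int],
    max_attempts: int = 200_000,
) -> None:
    """Drop random fiber segments into a column band until the band's
    foreground fraction reaches the target (rejection placement)."""
    c0, c1 = cols
    if c1 <= c0 or target <= 0:
        return
    h = mask.shape[0]
    region_px = h * (c1 - c0)
    # sample segment origins from a box padded by the max segment length so
    # clipping at the region border leaves the density uniform to the edge
    pad = len_range[1]
    attempts = 0
    while mask[:, c0:c1].sum() / region_px < target:
        attempts += 1
        if attempts > max_attempts:
            raise SyntheticError(f"target fraction {target} unreachable in columns {cols}")
        r = int(rng.integers(-pad, h + pad))
        c = int(rng.integers(c0 - pad, c1 + pad))
        ang = rng.uniform(0, math.pi)
        length = rng.integers(len_range[0], len_range[1] + 1)
        r2 = int(round(r + length * math.sin(ang)))
        c2 = int(round(c + length * math.cos(ang)))
        rr, cc = _draw_line(r, c, r2, c2)
        keep = (rr >= 0) & (rr < h) & (cc >= c0) & (cc < c1)
        mask[rr[keep], cc[keep]] = True
        # 2 px thickness: repeat one row down
        rr2 = rr[keep] + 1
        ok = rr2 < h
        mask[rr2[ok], cc[keep][ok]] = True


def generate_fiber_image(params: FiberSceneParams = FiberSceneParams(), seed=0) -> FiberScene:
    """Synthesize a fiber image, its ground-truth mask, and the layer
    annotation with the true interface gap width."""
    rng = _rng(seed)
    gap_px = int(round(params.gap_width_um / params.pixel_size_um))
    adv_cols = (params.media_cols[1] + gap_px, params.width_px)
    mask = np.zeros((params.height_px, params.width_px), dtype=bool)
    _fill_region(mask, params.intima_cols, params.intima_fraction, rng, params.fiber_len_px)
    _fill_region(mask, params.media_cols, params.media_fraction, rng, params.fiber_len_px)
    gap_band = (params.media_cols[1], adv_cols[0])
    if gap_px > 0 and params.gap_fraction > 0:
        _fill_region(mask, gap_band, params.gap_fraction, rng, (5, 15))
    _fill_region(mask, adv_cols, params.adventitia_fraction, rng, params.fiber_len_px)

    raster = np.where(mask, params.fiber_level, params.background_level).astype(float)
    if params.noise_sd > 0:
        raster = raster + rng.normal(0.0, params.noise_sd, raster.shape)
    annotation = LayerAnnotation(
        intima=params.intima_cols, media=params.media_cols, adventitia=adv_cols
    )
    image = FiberImage(raster=raster, pixel_size_um=params.pixel_size_um, annotation=annotation)
    roi = (0, params.height_px, 0, params.width_px)
    return FiberScene(
        image=image, mask=mask, annotation=annotation,
        true_gap_um=gap_px * params.pixel_size_um, roi=roi,
    )


# ---------------------------------------------------------------------------
# polarization stack generator
# ---------------------------------------------------------------------------

def generate_polarization_stack(
    a0: np.ndarray,
    retardance: np.ndarray,
    phi: np.ndarray,
    noise_sd: float = 0.0,
    seed=0,
    pixel_size_um: float = 1.0,
) -> PolarizationStack:
    """Forward model I_k = a0*(1 + r*sin(2*(theta_k - phi))) + noise."""
    a0 = np.asarray(a0, dtype=float)
    r = np.asarray(retardance, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise SyntheticError("relative retardance must lie in [0, 1]")
    rng = _rng(seed)
    theta = np.deg2rad(POLARIZER_ANGLES_DEG)[:, None, None]
    frames = a0[None] * (1.0 + r[None] * np.sin(2.0 * (theta - phi[None])))
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return PolarizationStack(frames=frames, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# abundance table generator
# ---------------------------------------------------------------------------

def generate_abundance_table(
    n_control: int = reference.N_PROTEOMICS["control"],
    n_ad: int = reference.N_PROTEOMICS["advanced_ad"],
    profile_control: dict[str, tuple[float, float]] | None = None,
    profile_ad: dict[str, tuple[float, float]] | None = None,
    n_background: int = 0,
    background_log2_effects: dict[str, float] | None = None,
    background_log2_sd: float = 0.5,
    total_collagen: float = 1e6,
    sample_scale_log2_sd: float = 0.3,
    seed=0,
) -> tuple[AbundanceTable, dict]:
    """Log-normal abundance table with group-specific collagen composition.

    Collagen-type percentages per sample are drawn around each group's
    profile as a Gaussian composition conditioned on the sum-to-100
    closure (types are necessarily correlated: percentages sum to 100, so
    marginal SDs shrink by the closure factor), floored at a small
    positive value, and scaled by a per-sample log-normal total; one
    protein per collagen type.  Optional background (non-collagen) proteins get log-normal
    abundances with group log2 effects from ``background_log2_effects``.

    Returns the table and a ground-truth dict (profiles used, true
    differential background proteins).
    """
    rng = _rng(seed)
    if profile_control is None:
        profile_control = reference.COLLAGEN_PROFILE_CONTROL
    if profile_ad is None:
        profile_ad = profile_control  # null default: identical groups
    if set(profile_ad) != set(profile_control):
        raise SyntheticError("profiles must cover the same collagen types")
    types = list(profile_control)
    samples = [f"CTRL{i+1}" for i in range(n_control)] + [f"AD{i+1}" for i in range(n_ad)]
    groups = pd.Series(
        ["control"] * n_control + ["AD"] * n_ad, index=samples, name="group"
    )

    rows = {}
    for ctype in types:
        rows[f"COL_{ctype}"] = np.empty(len(samples))
    pcts = np.empty((len(types), len(samples)))
    for j, s in enumerate(samples):
        profile = profile_control if groups[s] == "control" else profile_ad
        mus = np.array([profile[t][0] for t in types])
        sds = np.array([profile[t][1] for t in types])
        dev = rng.normal(0.0, sds)
        # condition the independent draws on a zero-sum deviation (the
        # closure constraint of compositional data)
        dev -= sds**2 * dev.sum() / (sds**2).sum()
        draws = np.maximum(mus + dev, 1e-4)
        draws = draws / draws.sum() * 100.0
        scale = total_collagen * 2.0 ** rng.normal(0.0, sample_scale_log2_sd)
        pcts[:, j] = draws
        for i, t in enumerate(types):
            rows[f"COL_{t}"][j] = draws[i] / 100.0 * scale

    for k in range(n_background):
        name = f"PROT{k+1}"
        base = 2.0 ** rng.uniform(10, 20)
        eff = (background_log2_effects or {}).get(name, 0.0)
        vals = base * 2.0 ** rng.normal(0.0, background_log2_sd, len(samples))
        vals[n_control:] *= 2.0**eff
        rows[name] = vals

    data = pd.DataFrame(rows, index=samples).T
    collagen = pd.Series(
        {f"COL_{t}": t for t in types} | {f"PROT{k+1}": np.nan for k in range(n_background)},
        name="collagen_type",
    ).reindex(data.index)
    truth = {
        "profile_control": profile_control,
        "profile_ad": profile_ad,
        "true_percentages": pd.DataFrame(pcts, index=types, columns=samples),
        "differential_background": {
            k: v for k, v in (background_log2_effects or {}).items() if v != 0.0
        },
    }
    return AbundanceTable(data=data, groups=groups, collagen_type=collagen), truth
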