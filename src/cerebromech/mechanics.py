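"""Extension–inflation kinematics and wall stress for thin-walled arteries.

Turns pressure-myograph recordings (transmural pressure, deformed outer
diameter, axial force) plus an undeformed reference geometry into
circumferential/axial stretches and mean Cauchy wall stresses, assuming an
incompressible, circular, thin-walled cylinder:

    r_i     = sqrt(r_o^2 - (R_o^2 - R_i^2) / lambda_z)
    lam_th  = (r_o + r_i) / (R_o + R_i)                  (mid-wall stretch)
    sig_th  = P * r_i / (r_o - r_i)
    sig_z   = (f_T + P * pi * r_i^2) / (pi * (r_o - r_i) * (r_i + r_o))

Also locates the in vivo axial stretch ratio: the axial stretch at which
the axial force is insensitive to pressurization.

Unit convention (single, declared): pressures stored in mmHg and converted
at 133.322 Pa/mmHg; forces stored in mN; lengths in um (radii) and mm
(segment lengths); stresses reported in kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

MMHG_TO_PA = 133.322
#: relative tolerance at which the incompressibility identity must close
INCOMPRESSIBILITY_RTOL = 1e-12


class MechanicsError(ValueError):
    """Base class for non-physical mechanics input."""


class WallGeometryError(MechanicsError):
    """Raised when the wall would be thicker than the lumen allows."""


class DegenerateWallError(MechanicsError):
    """Raised when r_o == r_i (zero wall thickness)."""


class NonIdentifiableError(MechanicsError):
    """Raised when the in vivo stretch objective is flat across candidates."""


@dataclass(frozen=True)
class RingGeometry:
    """Undeformed reference state of one artery segment.

    Radii derive from traced ring perimeters assuming a circular
    cross-section, R = perimeter / (2*pi); two end rings, when supplied,
    are averaged arithmetically.
    """

    outer_perimeter_um: float
    inner_perimeter_um: float
    unloaded_length_mm: float

    def __post_init__(self) -> None:
        if not (self.outer_perimeter_um > self.inner_perimeter_um > 0):
            raise MechanicsError(
                "require outer_perimeter > inner_perimeter > 0, got "
                f"{self.outer_perimeter_um} / {self.inner_perimeter_um}"
            )
        if not self.unloaded_length_mm > 0:
            raise MechanicsError("unloaded length must be positive")

    @property
    def R_o_um(self) -> float:
        return self.outer_perimeter_um / (2.0 * math.pi)

    @property
    def R_i_um(self) -> float:
        return self.inner_perimeter_um / (2.0 * math.pi)

    @property
    def thickness_um(self) -> float:
        """Undeformed wall thickness R_o - R_i."""
        return self.R_o_um - self.R_i_um

    @classmethod
    def from_radii(cls, R_o_um: float, R_i_um: float, unloaded_length_mm: float) -> "RingGeometry":
        return cls(2.0 * math.pi * R_o_um, 2.0 * math.pi * R_i_um, unloaded_length_mm)

    @classmethod
    def from_rings(
        cls,
        outer_perimeters_um: Sequence[float],
        inner_perimeters_um: Sequence[float],
        unloaded_length_mm: float,
    ) -> "RingGeometry":
        """Average the per-ring perimeters of the (usually two) end rings."""
        return cls(
            float(np.mean(outer_perimeters_um)),
            float(np.mean(inner_perimeters_um)),
            unloaded_length_mm,
        )


def compute_inner_radius(geometry: RingGeometry, r_o_um: float, lambda_z: float) -> float:
    """Deformed inner radius from incompressibility.

    r_i = sqrt(r_o^2 - (R_o^2 - R_i^2)/lambda_z).  Raises
    :class:`WallGeometryError` when the wall volume exceeds what the
    measured outer radius can enclose (sqrt argument <= 0) instead of
    returning NaN.
    """
    if lambda_z <= 0:
        raise MechanicsError(f"lambda_z must be positive, got {lambda_z}")
    arg = r_o_um**2 - (geometry.R_o_um**2 - geometry.R_i_um**2) / lambda_z
    if arg <= 0:
        raise WallGeometryError(
            f"wall thicker than lumen: r_o={r_o_um} um cannot enclose the "
            f"reference wall volume at lambda_z={lambda_z}"
        )
    return math.sqrt(arg)


def compute_circ_stretch(geometry: RingGeometry, r_o_um: float, r_i_um: float) -> float:
    """Mid-wall circumferential stretch (r_o + r_i)/(R_o + R_i)."""
    if not (r_o_um > r_i_um > 0):
        raise MechanicsError(f"require r_o > r_i > 0, got {r_o_um}, {r_i_um}")
    return (r_o_um + r_i_um) / (geometry.R_o_um + geometry.R_i_um)


def compute_stresses(
    P_mmHg: float, r_i_um: float, r_o_um: float, f_T_mN: float
) -> tuple[float, float]:
    """Mean circumferential and axial Cauchy stresses, in kPa.

    sigma_theta = P*r_i/(r_o - r_i);
    sigma_z = (f_T + P*pi*r_i^2) / (pi*(r_o - r_i)*(r_i + r_o)).
    """
    if r_o_um == r_i_um:
        raise DegenerateWallError("zero wall thickness: r_o == r_i")
    P_pa = P_mmHg * MMHG_TO_PA
    r_i = r_i_um * 1e-6
    r_o = r_o_um * 1e-6
    f_T = f_T_mN * 1e-3
    sigma_theta = P_pa * r_i / (r_o - r_i)
    sigma_z = (f_T + P_pa * math.pi * r_i**2) / (math.pi * (r_o - r_i) * (r_i + r_o))
    return sigma_theta / 1e3, sigma_z / 1e3


@dataclass
class InflationRecord:
    """One pressure step of an extension–inflation protocol, with derived
    kinematics and stresses filled in by :func:`analyze_cycle`."""

    P_mmHg: float
    r_o_um: float
    f_T_mN: float
    lambda_z: float
    r_i_um: float = float("nan")
    lambda_theta: float = float("nan")
    lambda_theta_norm: float = float("nan")
    sigma_theta_kPa: float = float("nan")
    sigma_z_kPa: float = float("nan")

    @property
    def P_Pa(self) -> float:
        return self.P_mmHg * MMHG_TO_PA

    @property
    def f_T_N(self) -> float:
        return self.f_T_mN * 1e-3


@dataclass
class InflationCycle:
    """An ordered limb of inflation records sharing one reference geometry."""

    geometry: RingGeometry
    records: list[InflationRecord]
    direction: str = "unloading"  # depressurization limb is the analysis default

    def __post_init__(self) -> None:
        pressures = [r.P_mmHg for r in self.records]
        diffs = np.diff(pressures)
        if len(pressures) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise MechanicsError("pressures must be strictly monotone within a limb")

    @property
    def pressures_mmHg(self) -> np.ndarray:
        return np.array([r.P_mmHg for r in self.records])

    def record_at(self, P_mmHg: float) -> InflationRecord:
        for r in self.records:
            if math.isclose(r.P_mmHg, P_mmHg, abs_tol=1e-9):
                return r
        raise KeyError(f"no record at {P_mmHg} mmHg")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_mmHg": [r.P_mmHg for r in self.records],
                "outer_radius_um": [r.r_o_um for r in self.records],
                "inner_radius_um": [r.r_i_um for r in self.records],
                "axial_force_mN": [r.f_T_mN for r in self.records],
                "lambda_z": [r.lambda_z for r in self.records],
                "lambda_theta": [r.lambda_theta for r in self.records],
                "lambda_theta_norm": [r.lambda_theta_norm for r in self.records],
                "sigma_theta_kPa": [r.sigma_theta_kPa for r in self.records],
                "sigma_z_kPa": [r.sigma_z_kPa for r in self.records],
            }
        )


def analyze_cycle(
    geometry: RingGeometry,
    pressures_mmHg: Sequence[float],
    outer_diameters_um: Sequence[float],
    axial_forces_mN: Sequence[float],
    stretched_length_mm: float,
    direction: str = "unloading",
) -> InflationCycle:
    """Build a fully derived cycle from raw myograph columns.

    The myograph reports outer *diameter*; radii, stretches and stresses
    are derived per record and the stretch series is normalized by the
    0 mmHg record of the limb.
    """
    lambda_z = stretched_length_mm / geometry.unloaded_length_mm
    records = []
    for P, d_o, f in zip(pressures_mmHg, outer_diameters_um, axial_forces_mN):
        r_o = d_o / 2.0
        r_i = compute_inner_radius(geometry, r_o, lambda_z)
        lam_th = compute_circ_stretch(geometry, r_o, r_i)
        s_th, s_z = compute_stresses(P, r_i, r_o, f)
        records.append(
            InflationRecord(
                P_mmHg=float(P),
                r_o_um=r_o,
                f_T_mN=float(f),
                lambda_z=lambda_z,
                r_i_um=r_i,
                lambda_theta=lam_th,
                sigma_theta_kPa=s_th,
                sigma_z_kPa=s_z,
            )
        )
    cycle = InflationCycle(geometry=geometry, records=records, direction=direction)
    return normalize_stretch(cycle)


def normalize_stretch(cycle: InflationCycle) -> InflationCycle:
    """Divide every circumferential stretch by the 0 mmHg stretch of the
    same limb, so the unloaded record normalizes to exactly 1."""
    try:
        ref = cycle.record_at(0.0)
    except KeyError:
        raise MechanicsError("cycle has no 0 mmHg record to normalize against") from None
    lam0 = ref.lambda_theta
    records = [replace(r, lambda_theta_norm=r.lambda_theta / lam0) for r in cycle.records]
    return InflationCycle(geometry=cycle.geometry, records=records, direction=cycle.direction)


def incompressibility_residual(cycle: InflationCycle) -> float:
    """Max relative error of lambda_z*(r_o^2 - r_i^2) = R_o^2 - R_i^2."""
    ref = cycle.geometry.R_o_um**2 - cycle.geometry.R_i_um**2
    worst = 0.0
    for r in cycle.records:
        lhs = r.lambda_z * (r.r_o_um**2 - r.r_i_um**2)
        worst = max(worst, abs(lhs - ref) / ref)
    return worst


def find_in_vivo_stretch(
    force_surface: Callable[[float, float], float],
    lambda_grid: Iterable[float] | None = None,
    pressure_sweep_mmHg: Iterable[float] | None = None,
    objective: str = "sd",
) -> float:
    """Axial stretch at which axial force varies least with pressure.

    Grid search: for each candidate lambda_z, evaluate the force surface
    over the pressure sweep and score its variation (sample SD by default,
    max-min range with ``objective="range"``).  Ties break toward the
    smaller stretch; a flat objective across all candidates means the in
    vivo stretch is not identifiable from the surface.
    """
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(1.00, 1.30 + 1e-9, 0.01), 10)
    if pressure_sweep_mmHg is None:
        pressure_sweep_mmHg = np.arange(0.0, 81.0, 10.0)
    grid = np.asarray(list(lambda_grid), dtype=float)
    sweep = np.asarray(list(pressure_sweep_mmHg), dtype=float)
    if grid.size < 3:
        raise MechanicsError("lambda grid must cover at least 3 candidates")
    if sweep.size < 2:
        raise MechanicsError("pressure sweep must contain >=2 pressures (variation undefined)")

    scores = np.empty(grid.size)
    for i, lz in enumerate(grid):
        forces = np.array([force_surface(lz, P) for P in sweep])
        if objective == "sd":
            scores[i] = float(np.std(forces, ddof=1))
        elif objective == "range":
            scores[i] = float(forces.max() - forces.min())
        else:
            raise ValueError(f"unknown objective {objective!r}")
    if math.isclose(scores.max(), scores.min(), rel_tol=1e-12, abs_tol=1e-12):
        raise NonIdentifiableError(
            "axial force variation is identical across all candidate stretches"
        )
    # argmin returns the first (smallest-lambda) minimizer: the tie-break rule
    return float(grid[int(np.argmin(scores))])
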