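"""Exponential stress–stretch fitting and tangent stiffness.

The circumferential stress–stretch curve of an artery limb is fitted with

    sigma(lam) = alpha * (exp(beta * (lam - 1)) - 1)

on the *normalized* circumferential stretch, so sigma(1) = 0 is built in
at the unloaded reference.  The tangent stiffness is the closed-form
derivative d sigma/d lam = alpha * beta * exp(beta * (lam - 1)); "tangent
stiffness at 80 mmHg" evaluates it at the normalized stretch of the
80 mmHg record.

Exposed both as a statsmodels-style model (``ExponentialStressModel`` /
``ExponentialStressResults``) and as the plain functions
:func:`fit_exponential` and :func:`tangent_stiffness`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mechanics import InflationCycle


@dataclass
class ExponentialFit:
    """Parameters of sigma = alpha*(exp(beta*(lam-1)) - 1)."""

    alpha_kPa: float
    beta: float
    residual_rms_kPa: float
    converged: bool
    lambda_ref: float = 1.0

    def predict(self, lam: float | np.ndarray) -> np.ndarray:
        return self.alpha_kPa * (np.exp(self.beta * (np.asarray(lam) - self.lambda_ref)) - 1.0)


class StiffnessDomainWarning(UserWarning):
    pass


def _model(params: np.ndarray, lam: np.ndarray) -> np.ndarray:
    a, b = params
    return a * (np.exp(b * (lam - 1.0)) - 1.0)


class ExponentialStressModel:
    """Least-squares exponential model of circumferential stress vs
    normalized circumferential stretch.

    Parameters
    ----------
    stress_kPa : array-like
        Circumferential Cauchy stress observations, kPa.
    stretch : array-like
        Normalized circumferential stretch (1 at the unloaded record).
    """

    def __init__(self, stress_kPa: Sequence[float], stretch: Sequence[float]):
        self.stress = np.asarray(stress_kPa, dtype=float)
        self.stretch = np.asarray(stretch, dtype=float)
        if self.stress.shape != self.stretch.shape:
            raise ValueError("stress and stretch must have equal length")
        if self.stress.size < 4:
            raise ValueError("need at least 4 points to fit the exponential")
        order = np.argsort(self.stretch)
        self.stretch = self.stretch[order]
        self.stress = self.stress[order]

    @classmethod
    def from_cycle(cls, cycle: InflationCycle, normalized: bool = True) -> "ExponentialStressModel":
        df = cycle.to_dataframe()
        lam = df["lambda_theta_norm"] if normalized else df["lambda_theta"]
        return cls(df["sigma_theta_kPa"].to_numpy(), lam.to_numpy())

    def _initial_guess(self) -> tuple[float, float]:
        lam, sig = self.stretch, self.stress
        # beta0 from the log-ratio of the last two stress increments,
        # alpha0 from matching the final point
        d1 = sig[-2] - sig[-3]
        d2 = sig[-1] - sig[-2]
        dl = lam[-1] - lam[-2]
        if d1 > 0 and d2 > 0 and dl > 0:
            beta0 = max(math.log(d2 / d1) / dl, 1e-3)
        else:
            beta0 = 5.0
        denom = math.expm1(beta0 * (lam[-1] - 1.0))
        alpha0 = sig[-1] / denom if denom > 0 and sig[-1] > 0 else max(abs(sig).max(), 1.0)
        return alpha0, beta0

    def fit(self) -> "ExponentialStressResults":
        sig = self.stress
        if np.allclose(sig, 0.0):
            fit = ExponentialFit(alpha_kPa=0.0, beta=0.0, residual_rms_kPa=0.0, converged=False)
            return ExponentialStressResults(self, fit, cov=None)
        a0, b0 = self._initial_guess()
        sol = least_squares(
            lambda p: _model(p, self.stretch) - sig,
            x0=[a0, b0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=2000,
        )
        resid = sol.fun
        rms = float(np.sqrt(np.mean(resid**2)))
        # declare non-convergence rather than return a silently bad fit
        scale = max(float(np.max(np.abs(sig))), 1e-12)
        converged = bool(sol.success) and sol.x[0] > 0 and sol.x[1] > 0 and rms < 0.25 * scale
        fit = ExponentialFit(
            alpha_kPa=float(sol.x[0]),
            beta=float(sol.x[1]),
            residual_rms_kPa=rms,
            converged=converged,
        )
        cov = None
        dof = sig.size - 2
        if converged and dof > 0:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.inv(jtj) * (resid @ resid) / dof
            except np.linalg.LinAlgError:
                cov = None
        return ExponentialStressResults(self, fit, cov=cov)


class ExponentialStressResults:
    """Fit results: parameter estimates, uncertainties, and the tangent
    stiffness evaluated anywhere along the curve."""

    def __init__(self, model: ExponentialStressModel, fit: ExponentialFit, cov: np.ndarray | None):
        self.model = model
        self.fit = fit
        self.cov = cov

    @property
    def params(self) -> dict[str, float]:
        return {"alpha_kPa": self.fit.alpha_kPa, "beta": self.fit.beta}

    @property
    def bse(self) -> dict[str, float]:
        if self.cov is None:
            return {"alpha_kPa": float("nan"), "beta": float("nan")}
        se = np.sqrt(np.diag(self.cov))
        return {"alpha_kPa": float(se[0]), "beta": float(se[1])}

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def predict(self, lam) -> np.ndarray:
        return self.fit.predict(lam)

    def tangent_stiffness(self, lambda_eval: float) -> float:
        return tangent_stiffness(self.fit, lambda_eval)

    def summary(self) -> str:
        f, se = self.fit, self.bse
        lines = [
            "Exponential stress-stretch fit: sigma = alpha*(exp(beta*(lam-1)) - 1)",
            f"  n points        : {self.model.stress.size}",
            f"  alpha [kPa]     : {f.alpha_kPa:.4g} (se {se['alpha_kPa']:.3g})",
            f"  beta  [-]       : {f.beta:.4g} (se {se['beta']:.3g})",
            f"  residual RMS    : {f.residual_rms_kPa:.4g} kPa",
            f"  converged       : {f.converged}",
            f"  tangent at lam=1: {f.alpha_kPa * f.beta:.4g} kPa",
        ]
        return "\n".join(lines)


def fit_exponential(points: Sequence[tuple[float, float]]) -> ExponentialFit:
    """Fit sigma = alpha*(exp(beta*(lam-1))-1) to (stretch, stress) pairs."""
    lam = [p[0] for p in points]
    sig = [p[1] for p in points]
    return ExponentialStressModel(sig, lam).fit().fit


def tangent_stiffness(fit: ExponentialFit, lambda_eval: float) -> float:
    """Closed-form d sigma/d lam = alpha*beta*exp(beta*(lam-1)), kPa."""
    if not fit.converged:
        raise ValueError("cannot evaluate tangent stiffness of a non-converged fit")
    if lambda_eval < fit.lambda_ref:
        warnings.warn(
            f"tangent stiffness evaluated at lambda={lambda_eval} below the "
            f"reference {fit.lambda_ref} (extrapolation)",
            StiffnessDomainWarning,
            stacklevel=2,
        )
    return fit.alpha_kPa * fit.beta * math.exp(fit.beta * (lambda_eval - fit.lambda_ref))


def tangent_vs_pressure(results: ExponentialStressResults, cycle: InflationCycle) -> pd.DataFrame:
    """Tangent stiffness at each recorded pressure of a limb."""
    df = cycle.to_dataframe()
    k = [results.tangent_stiffness(l) for l in df["lambda_theta_norm"]]
    return pd.DataFrame({"pressure_mmHg": df["pressure_mmHg"], "tangent_kPa": k})


def group_stiffness_curve(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SEM tangent stiffness across samples at matched pressures."""
    merged = pd.concat(tables)
    g = merged.groupby("pressure_mmHg")["tangent_kPa"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "tangent_mean_kPa", "sem": "tangent_sem_kPa", "count": "n"})
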