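"""Reversible Fab monomer-dimer self-association: equilibrium, isotherm
simulation and global fitting.

The model describes a monomer M and dimer D in rapid equilibrium with
dissociation constant ``K_D = [M]^2 / [D]`` (muM).  The experimental
observable is the weight-average sedimentation coefficient

    s_w(c) = ([M] s_M + 2 [D] s_D) / c_tot,

which rises from s_M at infinite dilution to s_D at saturation.  Fitting is
performed at the isotherm level — s_w versus loading concentration — which
shares the parameterization and identifiability structure of full boundary
fitting while remaining desk-scale.  The dimer molecular weight is fixed at
exactly twice the monomer's; K_D, s_M and s_D are floated.

Units: concentrations in muM monomer-equivalents, sedimentation
coefficients in Svedberg, molecular weights in Da.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NonConvergence, NonPositiveInput


@dataclass(frozen=True)
class SelfAssocModel:
    """Monomer-dimer equilibrium parameters.

    K_D in muM (defined [M]^2/[D]); s_M < s_D in Svedberg; MW_monomer in Da.
    The dimer MW is 2 x MW_monomer by construction.
    """

    K_D: float
    s_M: float
    s_D: float
    MW_monomer: float = 48000.0

    def __post_init__(self):
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")
        if not 0 < self.s_M < self.s_D:
            raise ValueError("require 0 < s_M < s_D")
        if self.MW_monomer <= 0:
            raise ValueError("MW_monomer must be positive")

    @property
    def MW_dimer(self) -> float:
        return 2.0 * self.MW_monomer


@dataclass(frozen=True)
class Isotherm:
    """Weight-average sedimentation coefficients across loading
    concentrations (muM monomer-equivalents)."""

    concentrations_uM: tuple[float, ...]
    s_w: tuple[float, ...]
    noise_sd: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        c = np.asarray(self.concentrations_uM)
        if len(c) != len(self.s_w):
            raise ValueError("concentration and s_w lengths differ")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations_uM)) != len(self.concentrations_uM):
            raise ValueError("concentrations must be distinct")

    def to_csv(self, path: str | Path) -> None:
        sd = self.noise_sd or [float("nan")] * len(self.s_w)
        pd.DataFrame(
            {"concentration_uM": self.concentrations_uM, "s_w": self.s_w, "sd": sd}
        ).to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Isotherm":
        df = pd.read_csv(path)
        sd = tuple(df["sd"]) if "sd" in df and df["sd"].notna().all() else ()
        return cls(
            concentrations_uM=tuple(df["concentration_uM"]),
            s_w=tuple(df["s_w"]),
            noise_sd=sd,
        )


@dataclass(frozen=True)
class FitResult:
    K_D: float
    s_M: float
    s_D: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""
    bootstrap_intervals: dict | None = None

    def model(self, MW_monomer: float = 48000.0) -> SelfAssocModel:
        return SelfAssocModel(K_D=self.K_D, s_M=self.s_M, s_D=self.s_D,
                              MW_monomer=MW_monomer)

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "K_D_uM": self.K_D, "s_M": self.s_M, "s_D": self.s_D,
            "rss": self.rss, "converged": self.converged,
            "n_points": self.n_points, "message": self.message, "seed": seed,
        }
        if self.bootstrap_intervals:
            payload["bootstrap_intervals"] = self.bootstrap_intervals
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# closed-form equilibrium
# ---------------------------------------------------------------------------

def mass_to_molar(conc_mg_ml: float, MW_monomer: float) -> float:
    """Convert mg/ml to muM monomer-equivalents (mg/ml = g/L; g/L / (g/mol)
    = mol/L; x 1e6 = muM).  Zero maps to zero; negatives are rejected."""
    if conc_mg_ml < 0 or MW_monomer <= 0:
        raise NonPositiveInput("concentration must be >= 0 and MW > 0")
    return conc_mg_ml / MW_monomer * 1e6


def equilibrium_species(K_D: float, c_tot: float) -> tuple[float, float, float]:
    """Free monomer, dimer and dimerized mass fraction at total monomer-
    equivalent concentration ``c_tot``.

    Solves the mass balance [M] + 2[M]^2/K_D = c_tot exactly:
    [M] = (-K_D + sqrt(K_D^2 + 8 K_D c_tot)) / 4,  [D] = [M]^2 / K_D.
    """
    if K_D <= 0:
        raise NonPositiveInput("K_D must be positive")
    if c_tot < 0:
        raise NonPositiveInput("c_tot must be non-negative")
    if c_tot == 0:
        return 0.0, 0.0, 0.0
    m = (-K_D + np.sqrt(K_D * K_D + 8.0 * K_D * c_tot)) / 4.0
    d = m * m / K_D
    return float(m), float(d), float(2.0 * d / c_tot)


def weight_average_s(model: SelfAssocModel, c_tot: float) -> float:
    """Weight-average sedimentation coefficient at ``c_tot`` (muM).

    Strictly increasing in concentration; tends to s_M as c -> 0 and to s_D
    as c -> infinity.
    """
    if c_tot <= 0:
        raise NonPositiveInput("c_tot must be positive")
    m, d, _ = equilibrium_species(model.K_D, c_tot)
    return float((m * model.s_M + 2.0 * d * model.s_D) / c_tot)


def simulate_isotherm(
    model: SelfAssocModel,
    concentrations_uM: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Simulate s_w observations with additive Gaussian noise.

    ``noise_sd`` may be a single Svedberg value applied to every point; a
    proportional scheme is obtained by passing per-point values computed by
    the caller (see :func:`proportional_noise_sd`).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = np.array([weight_average_s(model, c) for c in concentrations_uM])
    noisy = clean + rng.normal(0.0, noise_sd, size=len(clean)) if noise_sd > 0 else clean
    return Isotherm(
        concentrations_uM=tuple(float(c) for c in concentrations_uM),
        s_w=tuple(float(s) for s in noisy),
        noise_sd=tuple([float(noise_sd)] * len(clean)),
        seed=seed,
    )


def simulate_isotherm_proportional(
    model: SelfAssocModel,
    concentrations_uM: Sequence[float],
    rel_noise: float,
    seed: int | None = None,
) -> Isotherm:
    """Simulate s_w with noise proportional to the clean signal
    (sd = rel_noise x s_w)."""
    rng = np.random.default_rng(seed)
    clean = np.array([weight_average_s(model, c) for c in concentrations_uM])
    sd = rel_noise * clean
    noisy = clean + rng.normal(0.0, 1.0, size=len(clean)) * sd
    return Isotherm(
        concentrations_uM=tuple(float(c) for c in concentrations_uM),
        s_w=tuple(float(s) for s in noisy),
        noise_sd=tuple(float(x) for x in sd),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = ((1e-4, 0.1, 0.1), (1e4, 50.0, 50.0))  # (K_D, s_M, s_D)


def fit_monomer_dimer(
    iso: Isotherm,
    init: SelfAssocModel | None = None,
    bounds=_DEFAULT_BOUNDS,
    n_starts: int = 5,
    bootstrap: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Globally fit (K_D, s_M, s_D) to a weight-average isotherm by bounded
    nonlinear least squares with deterministic multi-start.

    The monomer MW is fixed (it does not enter the isotherm model).  An
    isotherm with no concentration dependence (flat within numerical noise,
    e.g. generated with s_M = s_D) is non-identifiable and raises
    :class:`NonConvergence` with diagnostics.

    ``bootstrap`` > 0 adds residual-bootstrap percentile intervals.
    """
    c = np.asarray(iso.concentrations_uM, dtype=float)
    y = np.asarray(iso.s_w, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least three loading concentrations")

    spread = float(y.max() - y.min())
    noise_scale = float(np.median(iso.noise_sd)) if iso.noise_sd else 0.0
    if spread <= max(1e-6, 0.1 * noise_scale):
        raise NonConvergence(
            "isotherm shows no concentration dependence; K_D is not identifiable "
            "(s_M = s_D or fully saturated/dilute design)",
            diagnostics={"s_w_spread": spread, "noise_scale": noise_scale},
        )

    def residuals(theta):
        kd, sm, sd_ = theta
        m = (-kd + np.sqrt(kd * kd + 8.0 * kd * c)) / 4.0
        d = m * m / kd
        return (m * sm + 2.0 * d * sd_) / c - y

    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    starts = _starting_points(iso, init, n_starts, lo, hi)
    best = None
    for theta0 in starts:
        sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    rss, sol = best
    kd, sm, sd_ = (float(v) for v in sol.x)
    converged = bool(sol.success) and sm < sd_
    if not converged:
        raise NonConvergence(
            f"fit did not converge: {sol.message}",
            diagnostics={"rss": rss, "estimates": {"K_D": kd, "s_M": sm, "s_D": sd_}},
        )

    intervals = None
    if bootstrap > 0:
        intervals = _residual_bootstrap(residuals, sol.x, c, y, lo, hi, bootstrap, seed)
    return FitResult(K_D=kd, s_M=sm, s_D=sd_, rss=rss, converged=True,
                     n_points=len(c), message=sol.message,
                     bootstrap_intervals=intervals)


def _starting_points(iso, init, n_starts, lo, hi):
    c = np.asarray(iso.concentrations_uM)
    y = np.asarray(iso.s_w)
    if init is not None:
        base = np.array([init.K_D, init.s_M, init.s_D])
    else:
        # data-driven guess: s_M ~ lowest observation, s_D ~ 1.5x highest,
        # K_D ~ geometric mean of loadings
        base = np.array([float(np.exp(np.mean(np.log(c)))),
                         float(y.min()) * 0.95, float(y.max()) * 1.3])
    rng = np.random.default_rng(20240120)  # deterministic multi-start
    starts = [base]
    for _ in range(n_starts - 1):
        jitter = np.exp(rng.normal(0.0, 0.5, size=3))
        starts.append(np.clip(base * jitter, lo * 1.01, hi * 0.99))
    return [np.clip(s, lo * 1.000001, hi * 0.999999) for s in starts]


def _residual_bootstrap(residuals, theta_hat, c, y, lo, hi, n_boot, seed):
    rng = np.random.default_rng(seed)
    fitted = y + residuals(theta_hat)  # model prediction = y + r where r = pred - y
    res = residuals(theta_hat)
    draws = {"K_D": [], "s_M": [], "s_D": []}
    for _ in range(n_boot):
        y_star = fitted - rng.choice(res, size=len(res), replace=True)
        def rb(theta, y_star=y_star):
            kd, sm, sd_ = theta
            m = (-kd + np.sqrt(kd * kd + 8.0 * kd * c)) / 4.0
            d = m * m / kd
            return (m * sm + 2.0 * d * sd_) / c - y_star
        sol = least_squares(rb, theta_hat, bounds=(lo, hi), method="trf")
        for key, v in zip(("K_D", "s_M", "s_D"), sol.x):
            draws[key].append(float(v))
    return {
        k: [float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))]
        for k, v in draws.items()
    }
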