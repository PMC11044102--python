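"""Retention laws and gradient-elution retention prediction.

Two single-dimension retention laws are supported, each mapping the
volume fraction ``phi`` of the dimension's *strong* eluting solvent to a
retention factor ``k``:

* linear solvent strength (LSS), the standard law for reversed-phase
  gradients: ``k(phi) = k0 * exp(-S * phi)``;
* the adsorption model, the standard law for HILIC:
  ``k(phi) = k100 * phi**(-n)``.

``phi`` is always the fraction of the strong solvent *of that dimension*
(water for HILIC, acetonitrile for RP-LC); conversion between the two
conventions is performed explicitly in :mod:`lcxlc.metrics`.

Gradient retention times are obtained by numerically solving the general
gradient-elution integral

    integral_0^(tR - t0)  dt / (t0 * k(phi_inlet(t)))  =  1

where ``phi_inlet(t)`` is the programmed composition delayed by the dwell
volume.  Retention parameters can be fitted from multi-gradient
observations by derivative-free simplex minimization, mirroring the
standard practice of running 3-4 gradients whose slopes differ by a
constant factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "RetentionModel",
    "VanDeemterCurve",
    "Analyte",
    "GradientProgram",
    "GradientElution",
    "FitResult",
    "NotElutedWarning",
    "retention_factor",
    "plate_count",
    "composition_at_inlet",
    "predict_gradient_retention",
    "local_k_at_elution",
    "fit_retention_parameters",
]


class NotElutedWarning(UserWarning):
    """An analyte did not elute within the configured horizon."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionModel:
    """Single-dimension retention law.

    Parameters
    ----------
    kind:
        ``"lss"`` or ``"adsorption"``.
    p1:
        ``k0`` for LSS (retention factor at phi = 0) or ``k100`` for the
        adsorption model (retention factor at phi = 1).
    p2:
        ``S`` (LSS slope) or ``n`` (number of displaced strong-solvent
        molecules).
    """

    kind: str
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.kind not in ("lss", "adsorption"):
            raise ValueError(f"unknown retention-law kind {self.kind!r}")
        if self.p1 <= 0:
            raise ValueError("k0 / k100 must be positive")
        if self.p2 < 0:
            raise ValueError("S / n must be non-negative")

    @classmethod
    def lss(cls, k0: float, S: float) -> "RetentionModel":
        return cls("lss", k0, S)

    @classmethod
    def adsorption(cls, k100: float, n: float) -> "RetentionModel":
        return cls("adsorption", k100, n)

    def k(self, phi: float | np.ndarray) -> float | np.ndarray:
        return retention_factor(self, phi)


@dataclass(frozen=True)
class VanDeemterCurve:
    """Plate-height curve H(u) = a + b/u + c*u.

    ``a`` in µm, ``b`` in µm·mm/s, ``c`` in µm·s/mm; ``u`` in mm/s.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("van Deemter coefficients must be non-negative")
        if self.a == 0 and self.b == 0 and self.c == 0:
            raise ValueError("plate height is identically zero")

    def plate_height(self, u: float) -> float:
        """Plate height in µm at linear velocity ``u`` (mm/s)."""
        if u <= 0:
            raise ValueError("linear velocity must be positive")
        return self.a + (self.b / u if self.b else 0.0) + self.c * u


@dataclass(frozen=True)
class Analyte:
    """One compound with its retention and plate-height parameters in both dimensions."""

    name: str
    model_d1: RetentionModel
    model_d2: RetentionModel
    vd_d1: VanDeemterCurve
    vd_d2: VanDeemterCurve


@dataclass(frozen=True)
class GradientProgram:
    """Linear solvent gradient delivered by one pump.

    The programmed composition ramps linearly from ``phi_init`` to
    ``phi_final`` over ``t_grad`` minutes, after an optional isocratic
    hold, and is held at ``phi_final`` afterwards.  The program reaches
    the column inlet delayed by ``dwell_volume / flow``.
    """

    phi_init: float
    phi_final: float
    t_grad: float  # min
    flow: float  # µL/min
    dwell_volume: float = 0.0  # µL
    hold_init: float = 0.0  # min

    def __post_init__(self) -> None:
        for phi in (self.phi_init, self.phi_final):
            if not 0.0 <= phi <= 1.0:
                raise ValueError("solvent fractions must lie in [0, 1]")
        if self.t_grad <= 0:
            raise ValueError("gradient time must be positive")
        if self.flow <= 0:
            raise ValueError("flow must be positive")
        if self.dwell_volume < 0 or self.hold_init < 0:
            raise ValueError("dwell volume and hold must be non-negative")

    @property
    def dwell_time(self) -> float:
        """Gradient delay caused by the dwell volume, in minutes."""
        return self.dwell_volume / self.flow

    @property
    def delay(self) -> float:
        """Total pre-ramp delay at the column inlet, in minutes."""
        return self.dwell_time + self.hold_init


class GradientElution(NamedTuple):
    """Outcome of a gradient retention-time prediction."""

    t_r: float  # min; meaningful only when eluted
    eluted: bool


@dataclass
class FitResult:
    """Fitted retention model plus fit diagnostics."""

    model: RetentionModel
    residuals: np.ndarray  # predicted - observed tR, min
    sse: float
    converged: bool
    n_iter: int
    message: str = ""


# ---------------------------------------------------------------------------
# Retention laws
# ---------------------------------------------------------------------------


def retention_factor(model: RetentionModel, phi):
    """Retention factor at strong-solvent fraction ``phi``.

    LSS: ``k0 * exp(-S*phi)``; adsorption: ``k100 * phi**(-n)``.  The
    adsorption law diverges at ``phi = 0`` and is a domain error there.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > 1):
        raise ValueError("phi must lie in [0, 1]")
    if model.kind == "lss":
        out = model.p1 * np.exp(-model.p2 * phi_arr)
    else:
        if np.any(phi_arr == 0) and model.p2 > 0:
            raise ValueError("adsorption retention diverges at phi = 0")
        out = model.p1 * phi_arr ** (-model.p2)
    return out if isinstance(phi, np.ndarray) else float(out)


def plate_count(curve: VanDeemterCurve, linear_velocity: float, length: float) -> float:
    """Plate count N = L / H(u) for a column of ``length`` mm at ``u`` mm/s."""
    if length <= 0:
        raise ValueError("column length must be positive")
    h_um = curve.plate_height(linear_velocity)
    return length * 1000.0 / h_um  # mm -> µm


def composition_at_inlet(gradient: GradientProgram, t) -> float | np.ndarray:
    """Strong-solvent fraction at the column inlet at time ``t`` (min).

    The programmed ramp is delayed by the dwell time plus any initial
    hold; composition is held at ``phi_final`` after the ramp ends.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    frac = np.clip((t_arr - gradient.delay) / gradient.t_grad, 0.0, 1.0)
    out = gradient.phi_init + frac * (gradient.phi_final - gradient.phi_init)
    return out if isinstance(t, np.ndarray) else float(out)


# ---------------------------------------------------------------------------
# Gradient retention-time prediction
# ---------------------------------------------------------------------------


def default_horizon(gradient: GradientProgram, t0: float) -> float:
    """Default elution horizon: 10 x (gradient time + dead time + delay)."""
    return 10.0 * (gradient.t_grad + t0 + gradient.delay)


def _cumulative_integral(model, gradient, t0, horizon, n):
    """Cumulative value of the gradient-elution integral on an n-point grid.

    The grid includes the integrand's breakpoints (end of delay, end of
    ramp) so the trapezoid rule never straddles a kink.
    """
    base = np.linspace(0.0, horizon, n)
    knots = [gradient.delay, gradient.delay + gradient.t_grad]
    extra = [k for k in knots if 0.0 < k < horizon]
    tau = np.unique(np.concatenate([base, extra]))
    phi = composition_at_inlet(gradient, tau)
    if model.kind == "adsorption":
        phi = np.maximum(phi, 1e-12)  # analyte simply immobile in pure weak solvent
        k = model.p1 * phi ** (-model.p2)
    else:
        k = model.p1 * np.exp(-model.p2 * phi)
    integrand = 1.0 / (t0 * k)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(tau) * 0.5 * (integrand[:-1] + integrand[1:]))])
    return tau, cum


def predict_gradient_retention(
    model: RetentionModel,
    gradient: GradientProgram,
    t0: float,
    horizon: float | None = None,
    tol_min: float = 1e-4,
) -> GradientElution:
    """Gradient-elution retention time by adaptive quadrature.

    Solves ``integral_0^(tR-t0) dt / (t0 k(phi_inlet(t))) = 1`` on a grid
    that is refined (doubled) until the located retention time changes by
    less than ``tol_min`` minutes.  Returns a flagged non-elution result
    if the integral does not reach 1 within the horizon.
    """
    if t0 <= 0:
        raise ValueError("dead time t0 must be positive")
    if horizon is None:
        horizon = default_horizon(gradient, t0)

    def locate(n: int) -> float | None:
        tau, cum = _cumulative_integral(model, gradient, t0, horizon, n)
        if cum[-1] < 1.0:
            return None
        j = int(np.searchsorted(cum, 1.0))
        # linear interpolation of the cumulative integral inside one cell
        c0, c1 = cum[j - 1], cum[j]
        frac = (1.0 - c0) / (c1 - c0) if c1 > c0 else 0.0
        return tau[j - 1] + frac * (tau[j] - tau[j - 1])

    n = 2049
    prev = locate(n)
    if prev is None:
        return GradientElution(math.nan, False)
    for _ in range(14):
        n = 2 * (n - 1) + 1
        cur = locate(n)
        if cur is None:  # pragma: no cover - cannot lose elution on refinement
            return GradientElution(math.nan, False)
        if abs(cur - prev) < tol_min:
            return GradientElution(t0 + cur, True)
        prev = cur
    return GradientElution(t0 + prev, True)


def local_k_at_elution(
    model: RetentionModel, gradient: GradientProgram, t_r: float, t0: float
) -> float:
    """Local retention factor at the column exit at elution.

    The composition present at the exit at time ``tR`` left the inlet one
    unretained traversal earlier, i.e. at ``tR - t0``.
    """
    if t_r < t0:
        raise ValueError("tR must be at least t0")
    phi = composition_at_inlet(gradient, t_r - t0)
    if model.kind == "adsorption":
        phi = max(phi, 1e-12)
    return float(retention_factor(model, phi))


# ---------------------------------------------------------------------------
# Parameter fitting from multi-gradient data
# ---------------------------------------------------------------------------


def fit_retention_parameters(
    observations: Sequence[tuple[GradientProgram, float]],
    kind: str,
    t0: float,
    grid_size: int = 12,
) -> FitResult:
    """Fit (k0, S) or (k100, n) from gradient retention times.

    Sum-of-squared-residual minimization by Nelder-Mead simplex on
    log-transformed parameters, seeded from the best point of a coarse
    log-spaced grid scan.  At least two observations with distinct
    gradient slopes are required.
    """
    if kind not in ("lss", "adsorption"):
        raise ValueError(f"unknown retention-law kind {kind!r}")
    obs = list(observations)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    slopes = {
        round((g.phi_final - g.phi_init) / g.t_grad, 12) for g, _ in obs
    }
    if len(slopes) < 2:
        raise ValueError("need at least 2 observations with distinct gradient slopes")

    t_obs = np.array([t for _, t in obs], dtype=float)

    def predict(p1: float, p2: float) -> np.ndarray:
        model = RetentionModel(kind, p1, p2)
        out = np.empty(len(obs))
        for i, (g, _) in enumerate(obs):
            res = predict_gradient_retention(model, g, t0)
            out[i] = res.t_r if res.eluted else 1e6
        return out

    def sse(logp: np.ndarray) -> float:
        p1, p2 = np.exp(logp)
        r = predict(p1, p2) - t_obs
        return float(r @ r)

    # coarse log-grid seed
    p1_grid = np.logspace(-2, 4, grid_size)
    p2_grid = np.logspace(-1, 2, grid_size)
    best, best_val = None, np.inf
    for p1 in p1_grid:
        for p2 in p2_grid:
            v = sse(np.log([p1, p2]))
            if v < best_val:
                best, best_val = (p1, p2), v

    res = minimize(
        sse,
        np.log(best),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    p1, p2 = np.exp(res.x)
    model = RetentionModel(kind, float(p1), float(p2))
    residuals = predict(p1, p2) - t_obs
    if not res.success:
        warnings.warn(f"retention fit did not converge: {res.message}")
    return FitResult(
        model=model,
        residuals=residuals,
        sse=float(residuals @ residuals),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )
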