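"""Rule-of-mixtures construction by constrained displacement-mismatch minimization.

For each cancer fraction l_c the heterogeneous rod's creep displacement
u_het(t) is matched by an equivalent homogeneous 1-term Prony material
(E_hm, D_hm, tau_hm) by minimizing

    J(E_hm, D_hm, tau_hm) = \\int_0^{t_exp} (u_het(t) - u_hom(t))^2 dt,
    subject to E_hm > 0, tau_hm > 0, 0 < D_hm < 1,

the displacement form of the strain-energy equivalence (Hill) condition for a
constant-stress test.  The integral is evaluated by the trapezoidal rule on a
grid with step ``dt`` (default 50 ms).  Tabulating the minimizer over a grid
of fractions from 0 to 1 yields the rule of mixtures l_c -> tau_hm used as
the diagnostic index.

Numerical strategy: the three unknowns are transformed to
(log E_hm, logit D_hm, log tau_hm), which enforces the positivity and D < 1
constraints by construction, and the minimization is run as a weighted
nonlinear least-squares problem (trust-region reflective) whose cost equals
the trapezoid integral exactly.  Five deterministic multi-starts guard
against local minima; rule construction additionally warm-starts each
fraction from the previous one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .materials import (
    LoadProtocol,
    PronyMaterial,
    RodSpecimen1D,
    rod_creep_displacement,
)

__all__ = [
    "ApparentFit",
    "MixtureRule",
    "ConstraintViolationError",
    "mismatch_objective",
    "fit_equivalent_homogeneous",
    "build_mixture_rule",
]

# clamp for the logit-transformed stiffness loss: D in (expit(-35), expit(35))
_XCLIP = 35.0


class ConstraintViolationError(ValueError):
    """A candidate apparent-parameter triple violates its positivity bounds."""


@dataclass
class ApparentFit:
    """Fitted 1-term Prony parameters of the equivalent homogeneous material.

    ``objective`` is the minimized trapezoid integral of the squared
    displacement mismatch (m^2 s) for rule fits, or the squared residual norm
    for trace fits.  ``E_hm`` may be None for normalized trace fits where the
    instantaneous modulus is not identifiable (no specimen geometry given).
    """

    E_hm: float | None
    D_hm: float
    tau_hm: float
    objective: float
    converged: bool = True
    n_restarts_used: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.E_hm is not None and not self.E_hm > 0:
            raise ValueError(f"E_hm must be positive, got {self.E_hm}")
        if not self.tau_hm > 0:
            raise ValueError(f"tau_hm must be positive, got {self.tau_hm}")
        if not 0.0 < self.D_hm < 1.0:
            raise ValueError(f"D_hm must lie in (0, 1), got {self.D_hm}")
        if not self.objective >= 0:
            raise ValueError("objective must be non-negative")

    def as_material(self, name: str = "apparent") -> PronyMaterial:
        if self.E_hm is None:
            raise ValueError("fit has no identified instantaneous modulus")
        return PronyMaterial(E0=self.E_hm, terms=((self.D_hm, self.tau_hm),),
                             name=name)

    def to_dict(self) -> dict:
        return {
            "E_hm_Pa": self.E_hm,
            "D_hm": self.D_hm,
            "tau_hm_s": self.tau_hm,
            "objective": self.objective,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApparentFit":
        return cls(E_hm=d["E_hm_Pa"], D_hm=d["D_hm"], tau_hm=d["tau_hm_s"],
                   objective=d["objective"], converged=d["converged"],
                   n_restarts_used=d.get("n_restarts_used", 0),
                   flags=tuple(d.get("flags", ())))


def integration_grid(t_exp: float, dt: float) -> np.ndarray:
    """Time grid 0..t_exp with step dt; the endpoint is always included."""
    t = np.arange(0.0, t_exp + 0.5 * dt, dt)
    if t[-1] < t_exp - 1e-12:
        t = np.append(t, t_exp)
    else:
        t[-1] = t_exp
    return t


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.zeros_like(t)
    d = np.diff(t)
    w[:-1] += 0.5 * d
    w[1:] += 0.5 * d
    return w


def _hom_displacement(theta, force, area, t):
    E, D, tau = theta
    Et = E * (1.0 - D * (1.0 - np.exp(-t / tau)))
    # same association as the rod compliance so endpoint mismatches vanish
    # identically, not merely to rounding
    return (force / area) * (1.0 / Et)


def mismatch_objective(
    candidate: Sequence[float],
    specimen: RodSpecimen1D,
    protocol: LoadProtocol,
    *,
    force: float | None = None,
    dt: float | None = None,
) -> float:
    """Trapezoid approximation of the squared displacement mismatch integral.

    ``candidate`` is the (E_hm, D_hm, tau_hm) triple of the trial homogeneous
    material.  The heterogeneous and homogeneous creep displacements are
    sampled on 0..hold_time with step ``dt`` (defaults to protocol.dt) and
    the integral of their squared difference is returned (m^2 s).

    Raises
    ------
    ConstraintViolationError
        If any candidate entry violates E_hm > 0, tau_hm > 0 or 0 < D_hm < 1.
    """
    E, D, tau = (float(x) for x in candidate)
    if E <= 0 or tau <= 0:
        raise ConstraintViolationError(
            f"E_hm and tau_hm must be positive, got E={E}, tau={tau}"
        )
    if not 0.0 < D < 1.0:
        raise ConstraintViolationError(f"D_hm must lie in (0, 1), got {D}")
    if force is None:
        force = protocol.magnitude if protocol.mode == "creep" else 1.0
    dt = protocol.dt if dt is None else dt
    t = integration_grid(protocol.hold_time, dt)
    u_het = rod_creep_displacement(specimen, force, t)
    u_hom = _hom_displacement((E, D, tau), force, specimen.area, t)
    return float(np.trapezoid((u_het - u_hom) ** 2, t))


def _pack(E: float, D: float, tau: float) -> np.ndarray:
    return np.array([np.log(E), np.clip(logit(D), -_XCLIP, _XCLIP), np.log(tau)])


def _unpack(x: np.ndarray) -> tuple[float, float, float]:
    E = float(np.exp(x[0]))
    D = float(expit(np.clip(x[1], -_XCLIP, _XCLIP)))
    tau = float(np.exp(x[2]))
    return E, D, tau


def _collapsed(material: PronyMaterial) -> np.ndarray:
    """Single-term start derived from a (possibly multi-term) constituent."""
    D = float(material.stiffness_losses.sum())
    tau = float(np.exp(np.mean(np.log(material.relaxation_times))))
    return _pack(material.E0, min(D, expit(_XCLIP)), tau)


def _default_starts(specimen: RodSpecimen1D) -> list[np.ndarray]:
    lc = specimen.cancer_fraction
    xh = _collapsed(specimen.healthy)
    xc = _collapsed(specimen.cancerous)
    xmid = 0.5 * (xh + xc)
    starts = [
        xh,                                     # healthy constituent
        xc,                                     # cancerous constituent
        (1.0 - lc) * xh + lc * xc,              # fraction-weighted blend
        np.array([xmid[0], 0.0, xmid[2]]),      # log-midpoint, D = 1/2
        (1.0 - lc) * xc + lc * xh,              # reverse-weighted blend
    ]
    return starts


def fit_equivalent_homogeneous(
    specimen: RodSpecimen1D,
    protocol: LoadProtocol,
    *,
    force: float | None = None,
    dt: float | None = None,
    warm_start: Sequence[float] | None = None,
    xtol: float = 1e-14,
) -> ApparentFit:
    """Fit the equivalent homogeneous 1-term Prony material for one fraction.

    Solves the constrained minimization of :func:`mismatch_objective` in the
    transformed variables (log E, logit D, log tau) from five deterministic
    starting points (plus an optional warm start), keeping the best local
    minimizer.  The returned objective never exceeds the objective at any of
    the starting points.
    """
    if protocol.hold_time < 10 * (protocol.dt if dt is None else dt):
        raise ValueError("hold_time must cover at least 10 integration steps")
    if force is None:
        force = protocol.magnitude if protocol.mode == "creep" else 1.0
    dt = protocol.dt if dt is None else dt
    t = integration_grid(protocol.hold_time, dt)
    sqw = np.sqrt(_trapezoid_weights(t))
    u_het = rod_creep_displacement(specimen, force, t)
    area = specimen.area

    def residuals(x):
        return sqw * (u_het - _hom_displacement(_unpack(x), force, area, t))

    starts = _default_starts(specimen)
    if warm_start is not None:
        E, D, tau = warm_start
        starts.append(_pack(E, D, tau))

    best = None
    best_cost = np.inf
    n_used = 0
    any_ok = False
    for x0 in starts:
        n_used += 1
        res = least_squares(residuals, x0, method="trf",
                            xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=400)
        any_ok = any_ok or res.status > 0
        cost = float(np.sum(res.fun**2))
        if cost < best_cost:
            best_cost = cost
            best = res
    E, D, tau = _unpack(best.x)
    flags = () if any_ok else ("optimizer_not_converged",)
    return ApparentFit(E_hm=E, D_hm=D, tau_hm=tau, objective=best_cost,
                       converged=any_ok, n_restarts_used=n_used, flags=flags)


@dataclass
class MixtureRule:
    """Tabulated rule of mixtures: fraction grid -> apparent (E, D, tau).

    Built by repeating the equivalent-homogeneous fit over an ascending
    fraction grid that starts at 0 (fully healthy) and ends at 1 (fully
    cancerous).  ``tau_values`` is the diagnostic column inverted by the
    characterization module.
    """

    fractions: np.ndarray
    fits: list[ApparentFit]
    protocol: LoadProtocol
    healthy: PronyMaterial
    cancerous: PronyMaterial
    dt_integration: float

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or len(self.fractions) != len(self.fits):
            raise ValueError("fractions and fits must have matching lengths")
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fraction grid must be strictly ascending")
        if abs(self.fractions[0]) > 1e-12 or abs(self.fractions[-1] - 1) > 1e-12:
            raise ValueError("fraction grid must start at 0 and end at 1")

    @property
    def tau_values(self) -> np.ndarray:
        return np.array([f.tau_hm for f in self.fits])

    @property
    def E_values(self) -> np.ndarray:
        return np.array([f.E_hm for f in self.fits])

    @property
    def D_values(self) -> np.ndarray:
        return np.array([f.D_hm for f in self.fits])

    @property
    def failed_fractions(self) -> np.ndarray:
        return self.fractions[[not f.converged for f in self.fits]]

    @property
    def is_partial(self) -> bool:
        return len(self.failed_fractions) > 0

    def content_hash(self) -> str:
        """Hash of constituents + protocol + grid + dt (cache/report key)."""
        payload = {
            "healthy": self.healthy.to_dict(),
            "cancerous": self.cancerous.to_dict(),
            "protocol": self.protocol.to_dict(),
            "fractions": [round(float(f), 12) for f in self.fractions],
            "dt_integration": self.dt_integration,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json_dict(self) -> dict:
        return {
            "healthy": self.healthy.to_dict(),
            "cancerous": self.cancerous.to_dict(),
            "protocol": self.protocol.to_dict(),
            "dt_integration_s": self.dt_integration,
            "fractions": self.fractions.tolist(),
            "fits": [f.to_dict() for f in self.fits],
            "rule_id": self.content_hash(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MixtureRule":
        return cls(
            fractions=np.asarray(d["fractions"], dtype=float),
            fits=[ApparentFit.from_dict(f) for f in d["fits"]],
            protocol=LoadProtocol.from_dict(d["protocol"]),
            healthy=PronyMaterial.from_dict(d["healthy"]),
            cancerous=PronyMaterial.from_dict(d["cancerous"]),
            dt_integration=d["dt_integration_s"],
        )

    @classmethod
    def load_json(cls, path) -> "MixtureRule":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "l_c": self.fractions,
            "E_hm_Pa": self.E_values,
            "D_hm": self.D_values,
            "tau_hm_s": self.tau_values,
            "converged": [f.converged for f in self.fits],
        })

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_fraction_grid(step: float = 0.01) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def build_mixture_rule(
    healthy: PronyMaterial,
    cancerous: PronyMaterial,
    protocol: LoadProtocol,
    fraction_grid: Sequence[float] | None = None,
    *,
    area: float = 1.0,
    dt: float | None = None,
) -> MixtureRule:
    """Build the rule of mixtures by solving the fit over a fraction grid.

    The grid must include 0 and 1 so the endpoints anchor the rule at the
    constituent parameters.  Each interior fraction is warm-started from the
    previous fraction's solution.  Rule construction always uses the creep
    (force-controlled) form of the mismatch functional, regardless of the
    mode the measured trace will use.
    """
    grid = (default_fraction_grid() if fraction_grid is None
            else np.sort(np.asarray(fraction_grid, dtype=float)))
    if abs(grid[0]) > 1e-12 or abs(grid[-1] - 1.0) > 1e-12:
        raise ValueError("fraction grid must include 0 and 1")
    dt = protocol.dt if dt is None else dt
    fits: list[ApparentFit] = []
    warm = None
    for lc in grid:
        spec = RodSpecimen1D(area=area, cancer_fraction=float(lc),
                             healthy=healthy, cancerous=cancerous)
        fit = fit_equivalent_homogeneous(spec, protocol, dt=dt, warm_start=warm)
        fits.append(fit)
        warm = (fit.E_hm, fit.D_hm, fit.tau_hm)
    return MixtureRule(fractions=grid, fits=fits, protocol=protocol,
                       healthy=healthy, cancerous=cancerous, dt_integration=dt)
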