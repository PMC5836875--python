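"""Viscoelastic constitutive laws and closed-form 1D biphasic rod responses.

Each tissue phase is a linear viscoelastic solid whose uniaxial relaxation
modulus is a Prony series,

    E(t) = E0 * (1 - sum_i D_i * (1 - exp(-t / tau_i))),

with instantaneous modulus ``E0`` (Pa), stiffness-loss fractions ``D_i``
(dimensionless, each in (0, 1), summing to less than 1 so the long-term
modulus stays positive) and relaxation times ``tau_i`` (s).

The 1D picture is a unit-length rod made of a "cancerous" segment of length
``l_c`` in series with a "healthy" segment of length ``1 - l_c``.  Under a
constant axial force the free-end displacement follows the quasi-elastic
compliance convention: the time-domain compliance of each phase is taken as
``1 / E(t)`` rather than the exact Laplace-domain creep compliance.  The rule
of mixtures built on top of these responses is self-consistent under that
convention, which is why it is adopted throughout the package.

All quantities are SI internally (Pa, m, s, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PronyMaterial",
    "RodSpecimen1D",
    "LoadProtocol",
    "relaxation_modulus",
    "rod_creep_displacement",
    "homogeneous_displacement",
]


@dataclass(frozen=True)
class PronyMaterial:
    """A phase's viscoelastic law: instantaneous modulus plus Prony terms.

    Parameters
    ----------
    E0 : float
        Instantaneous modulus, Pa.  Must be positive.
    terms : sequence of (D_i, tau_i) pairs
        Stiffness-loss fraction (dimensionless) and relaxation time (s) of
        each Prony term.  Relaxation times must be strictly increasing
        (canonical ordering); every ``D_i`` lies in (0, 1) and they sum to
        less than 1.
    name : str
        Free-text phase label (e.g. ``"healthy"``, ``"cancerous"``).
    """

    E0: float
    terms: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self) -> None:
        E0 = float(self.E0)
        terms = tuple((float(D), float(tau)) for D, tau in self.terms)
        object.__setattr__(self, "E0", E0)
        object.__setattr__(self, "terms", terms)
        if not np.isfinite(E0) or E0 <= 0:
            raise ValueError(f"instantaneous modulus must be positive, got {E0}")
        if not terms:
            raise ValueError("at least one Prony term is required")
        Ds = np.array([D for D, _ in terms])
        taus = np.array([tau for _, tau in terms])
        if np.any(~np.isfinite(Ds)) or np.any(~np.isfinite(taus)):
            raise ValueError("Prony terms must be finite")
        if np.any(taus <= 0):
            raise ValueError("every relaxation time must be positive")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("relaxation times must be strictly increasing")
        if np.any(Ds <= 0) or np.any(Ds >= 1):
            raise ValueError("every stiffness-loss fraction must lie in (0, 1)")
        if Ds.sum() >= 1:
            raise ValueError(
                "stiffness-loss fractions sum to "
                f"{Ds.sum():g} >= 1; long-term modulus would be non-positive"
            )

    @property
    def stiffness_losses(self) -> np.ndarray:
        """Array of D_i."""
        return np.array([D for D, _ in self.terms])

    @property
    def relaxation_times(self) -> np.ndarray:
        """Array of tau_i, s."""
        return np.array([tau for _, tau in self.terms])

    @property
    def long_term_modulus(self) -> float:
        """Asymptotic modulus E0 * (1 - sum D_i), Pa."""
        return self.E0 * (1.0 - self.stiffness_losses.sum())

    def relaxation_modulus(self, t):
        """Evaluate E(t), Pa, for scalar or array times t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        D = self.stiffness_losses
        tau = self.relaxation_times
        decay = (D[..., :] * (1.0 - np.exp(-t[..., None] / tau))).sum(axis=-1)
        out = self.E0 * (1.0 - decay)
        return out if out.ndim else float(out)

    def compliance(self, t):
        """Quasi-elastic compliance 1/E(t), 1/Pa."""
        return 1.0 / self.relaxation_modulus(t)

    def normalized_relaxation(self, t):
        """Dimensionless g(t) = E(t)/E0."""
        return self.relaxation_modulus(t) / self.E0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "E0_Pa": self.E0,
            "terms": [[D, tau] for D, tau in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PronyMaterial":
        return cls(E0=d["E0_Pa"], terms=tuple(tuple(t) for t in d["terms"]),
                   name=d.get("name", ""))


@dataclass(frozen=True)
class RodSpecimen1D:
    """Unit-length biphasic rod: a cancerous segment in series with a healthy one.

    ``cancer_fraction`` is the length fraction l_c of the cancerous segment;
    ``area`` is the cross-section A in m^2.
    """

    area: float
    cancer_fraction: float
    healthy: PronyMaterial
    cancerous: PronyMaterial

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"cross-section area must be positive, got {self.area}")
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise ValueError(
                f"cancer fraction must lie in [0, 1], got {self.cancer_fraction}"
            )


@dataclass(frozen=True)
class LoadProtocol:
    """Creep or stress-relaxation test definition.

    Parameters
    ----------
    mode : {"creep", "relaxation"}
        Creep imposes a constant force and records displacement; relaxation
        imposes a displacement and records reaction force.
    magnitude : float
        Applied force in N (creep) or imposed displacement in m (relaxation).
    ramp_time : float
        Linear loading ramp duration, s.  Zero means an ideal step.
    hold_time : float
        Hold duration t_exp, s — the characterization window.
    dt : float
        Sampling step, s (default 0.05, i.e. 50 ms).
    """

    mode: Literal["creep", "relaxation"]
    magnitude: float
    hold_time: float
    ramp_time: float = 0.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("creep", "relaxation"):
            raise ValueError(f"mode must be 'creep' or 'relaxation', got {self.mode!r}")
        if not self.hold_time > 0:
            raise ValueError("hold_time must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.dt > self.hold_time / 10:
            raise ValueError(
                f"dt={self.dt} too coarse: need dt <= hold_time/10 = "
                f"{self.hold_time / 10}"
            )
        if self.ramp_time < 0:
            raise ValueError("ramp_time must be non-negative")
        if not self.magnitude > 0:
            raise ValueError("load magnitude must be positive")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "magnitude": self.magnitude,
            "ramp_time_s": self.ramp_time,
            "hold_time_s": self.hold_time,
            "dt_s": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoadProtocol":
        return cls(mode=d["mode"], magnitude=d["magnitude"],
                   ramp_time=d.get("ramp_time_s", 0.0),
                   hold_time=d["hold_time_s"], dt=d.get("dt_s", 0.05))


def relaxation_modulus(material: PronyMaterial, t):
    """Relaxation modulus E(t), Pa.  ``t`` may be a scalar or array, t >= 0."""
    return material.relaxation_modulus(t)


def rod_creep_displacement(specimen: RodSpecimen1D, force: float, t):
    """Free-end displacement of the biphasic rod under constant force, m.

    u(t) = (F/A) * [ l_c / E_c(t) + (1 - l_c) / E_h(t) ]

    using the quasi-elastic compliance 1/E(t) for each phase.
    """
    if not force > 0:
        raise ValueError("force must be positive")
    lc = specimen.cancer_fraction
    u = (force / specimen.area) * (
        lc * specimen.cancerous.compliance(t)
        + (1.0 - lc) * specimen.healthy.compliance(t)
    )
    return u


def homogeneous_displacement(material: PronyMaterial, force: float, area: float, t):
    """Free-end displacement of the equivalent homogeneous rod, F/(A*E(t)), m."""
    if not force > 0:
        raise ValueError("force must be positive")
    if not area > 0:
        raise ValueError("area must be positive")
    return (force / area) * material.compliance(t)
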