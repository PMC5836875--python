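"""2D virtual-palpation simulator: linear viscoelastic plane-stress FE tests.

A rectangular sample is meshed with bilinear quadrilateral elements on a
regular grid; each element carries either the healthy or the cancerous
Prony material.  A rigid frictionless flat indenter covering one full edge
imposes a displacement ramp followed by a hold, and the total indenter
reaction force is recorded over time — a stress-relaxation "virtual
palpation" with known ground-truth tumor fraction.

Constitutive model: small-strain plane stress with a single scalar
relaxation function per element applied to both deviatoric and volumetric
response (constant Poisson ratio, default 0.45, for both phases), i.e.

    sigma(t) = C(E0, nu) * \\int_0^t g(t - s) d eps(s),
    g(t) = g_inf + sum_i D_i exp(-t / tau_i),  g_inf = 1 - sum_i D_i.

Under this convention a homogeneous sample in uniform uniaxial stress obeys
the 1D law E(t) exactly, which makes the closed-form rod solutions exact
oracles for the solver.  Time integration uses the exact exponential
recurrence for the internal variables h_i (exact for strain varying linearly
within a step); the effective stiffness is constant at fixed step size, so
the sparse factorization is computed once and reused for every step.

Boundary conditions: the indented edge has its normal displacement
prescribed and tangential displacement free (frictionless rigid platen); the
opposite edge is a frictionless support (normal displacement fixed), with a
single corner pinned tangentially to remove the rigid-body mode.  Lateral
edges are traction-free.  "posterior" indentation compresses the top edge
downward; "lateral" indentation is realized by transposing the label grid
(the material model is isotropic, so the two are exactly equivalent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .characterize import (
    ResponseTrace,
    estimate_fraction,
    fit_prony_1term,
    get_or_build_rule,
)
from .materials import LoadProtocol, PronyMaterial

__all__ = [
    "Microstructure2D",
    "PalpationBC",
    "generate_random_microstructure",
    "simulate_relaxation",
    "run_parametric_suite",
    "SuiteConfig",
]

HEALTHY, CANCEROUS = 0, 1
_MAX_ELEMENTS = 20000


@dataclass(frozen=True)
class Microstructure2D:
    """Regular element grid with per-element phase labels.

    ``labels`` has shape (ny, nx); row j is the j-th element row from the
    bottom of the domain.  Label 0 = healthy, 1 = cancerous.
    """

    nx: int
    ny: int
    element_size: float
    labels: np.ndarray
    target_fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.ny, self.nx):
            raise ValueError(
                f"labels shape {labels.shape} does not match (ny={self.ny}, nx={self.nx})"
            )
        if not np.all(np.isin(labels, (HEALTHY, CANCEROUS))):
            raise ValueError("labels must be 0 (healthy) or 1 (cancerous)")
        if not self.element_size > 0:
            raise ValueError("element_size must be positive")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if abs(self.realized_fraction - self.target_fraction) > 1.0 / labels.size + 1e-12:
            raise ValueError("realized fraction deviates from target by more "
                             "than one element")

    @property
    def realized_fraction(self) -> float:
        return float(np.count_nonzero(self.labels == CANCEROUS) / self.labels.size)

    def transposed(self) -> "Microstructure2D":
        return Microstructure2D(nx=self.ny, ny=self.nx,
                                element_size=self.element_size,
                                labels=self.labels.T.copy(),
                                target_fraction=self.target_fraction,
                                seed=self.seed)

    def save_text(self, path) -> None:
        """JSON header line followed by one label row per line (bottom row first)."""
        header = {
            "nx": self.nx, "ny": self.ny, "element_size_m": self.element_size,
            "seed": self.seed, "target_fraction": self.target_fraction,
            "realized_fraction": self.realized_fraction,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for row in self.labels:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def load_text(cls, path) -> "Microstructure2D":
        with open(path) as fh:
            header = json.loads(fh.readline())
            labels = np.array(
                [[int(v) for v in line.split()] for line in fh if line.strip()],
                dtype=np.int8,
            )
        return cls(nx=header["nx"], ny=header["ny"],
                   element_size=header["element_size_m"], labels=labels,
                   target_fraction=header["target_fraction"],
                   seed=header.get("seed"))

    def save_vtk(self, path) -> None:
        """Export the quad mesh with phase labels as legacy ASCII VTK."""
        nx, ny, h = self.nx, self.ny, self.element_size
        npts = (nx + 1) * (ny + 1)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("viscopalp microstructure\nASCII\nDATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {npts} float\n")
            for j in range(ny + 1):
                for i in range(nx + 1):
                    fh.write(f"{i * h:g} {j * h:g} 0\n")
            ncell = nx * ny
            fh.write(f"CELLS {ncell} {5 * ncell}\n")
            for j in range(ny):
                for i in range(nx):
                    n0 = j * (nx + 1) + i
                    fh.write(f"4 {n0} {n0 + 1} {n0 + nx + 2} {n0 + nx + 1}\n")
            fh.write(f"CELL_TYPES {ncell}\n")
            fh.write("\n".join(["9"] * ncell) + "\n")
            fh.write(f"CELL_DATA {ncell}\nSCALARS phase int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(v)) for v in self.labels.ravel()) + "\n")


@dataclass(frozen=True)
class PalpationBC:
    """Palpation boundary conditions: which edge the rigid platen indents.

    The opposite edge is always the frictionless support; the remaining two
    edges are free.  The platen is rigid, flat, frictionless and covers the
    full indented edge.
    """

    indented_edge: str = "posterior"
    constrained_edges: tuple[str, ...] = ("anterior",)

    def __post_init__(self) -> None:
        if self.indented_edge not in ("posterior", "lateral"):
            raise ValueError("indented_edge must be 'posterior' or 'lateral'")
        if self.indented_edge in self.constrained_edges:
            raise ValueError("indented edge cannot also be constrained")


class BoundaryConditionError(ValueError):
    """The constraint set leaves the system singular."""


def generate_random_microstructure(
    nx: int, ny: int, fraction: float, seed: int, element_size: float = 5e-4
) -> Microstructure2D:
    """Seeded random biphasic microstructure with an exact element count.

    Exactly ``round(fraction * nx * ny)`` elements are labeled cancerous,
    drawn uniformly without replacement from a generator seeded with
    ``seed``; the same arguments always give the same label grid.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = nx * ny
    n_c = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int8)
    if n_c:
        labels[rng.choice(n, size=n_c, replace=False)] = CANCEROUS
    return Microstructure2D(nx=nx, ny=ny, element_size=element_size,
                            labels=labels.reshape(ny, nx),
                            target_fraction=fraction, seed=seed)


# --- element matrices -------------------------------------------------------

_GAUSS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


def _plane_stress_C(nu: float) -> np.ndarray:
    return np.array([[1.0, nu, 0.0],
                     [nu, 1.0, 0.0],
                     [0.0, 0.0, (1.0 - nu) / 2.0]]) / (1.0 - nu**2)


def _element_matrices(h: float, nu: float):
    """B operators at the 4 Gauss points and the unit-modulus stiffness."""
    C = _plane_stress_C(nu)
    detJ = (h / 2.0) ** 2
    Bs = np.zeros((4, 3, 8))
    K = np.zeros((8, 8))
    for g, (xi, eta) in enumerate(_GAUSS):
        dN = 0.25 * np.array([
            [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
            [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
        ])
        dNxy = (2.0 / h) * dN
        B = np.zeros((3, 8))
        B[0, 0::2] = dNxy[0]
        B[1, 1::2] = dNxy[1]
        B[2, 0::2] = dNxy[1]
        B[2, 1::2] = dNxy[0]
        Bs[g] = B
        K += B.T @ C @ B * detJ
    return Bs, C, K, detJ


def _mesh_arrays(nx: int, ny: int):
    elems = np.empty((nx * ny, 4), dtype=np.int64)
    e = 0
    for j in range(ny):
        base = j * (nx + 1)
        for i in range(nx):
            n0 = base + i
            elems[e] = (n0, n0 + 1, n0 + nx + 2, n0 + nx + 1)
            e += 1
    edofs = np.empty((nx * ny, 8), dtype=np.int64)
    edofs[:, 0::2] = 2 * elems
    edofs[:, 1::2] = 2 * elems + 1
    return elems, edofs


def _material_arrays(micro, healthy, cancerous):
    mats = (healthy, cancerous)
    n_terms = max(len(m.terms) for m in mats)
    lab = micro.labels.ravel()
    E0 = np.empty(lab.size)
    D = np.zeros((lab.size, n_terms))
    tau = np.ones((lab.size, n_terms))
    for phase, m in enumerate(mats):
        sel = lab == phase
        E0[sel] = m.E0
        for i, (Di, ti) in enumerate(m.terms):
            D[sel, i] = Di
            tau[sel, i] = ti
    return E0, D, tau


def simulate_relaxation(
    micro: Microstructure2D,
    healthy: PronyMaterial,
    cancerous: PronyMaterial,
    protocol: LoadProtocol,
    bc: PalpationBC | None = None,
    *,
    nu: float = 0.45,
) -> ResponseTrace:
    """Quasi-static plane-stress relaxation test; returns force vs time.

    The platen displacement ramps linearly from 0 to ``protocol.magnitude``
    over ``ramp_time`` (an ideal step when ramp_time = 0), then holds for
    ``hold_time``.  The returned trace samples the total compressive platen
    reaction at every ``protocol.dt``, ramp included.
    """
    if protocol.mode != "relaxation":
        raise ValueError("simulate_relaxation requires a relaxation protocol")
    if micro.nx * micro.ny > _MAX_ELEMENTS:
        raise ValueError(f"mesh too large for a direct solve "
                         f"({micro.nx * micro.ny} > {_MAX_ELEMENTS} elements)")
    bc = bc or PalpationBC()
    if bc.indented_edge == "lateral":
        micro = micro.transposed()

    nx, ny, h = micro.nx, micro.ny, micro.element_size
    n_nodes = (nx + 1) * (ny + 1)
    ndof = 2 * n_nodes
    _, edofs = _mesh_arrays(nx, ny)
    Bs, C, K_unit, detJ = _element_matrices(h, nu)
    E0, D, tau = _material_arrays(micro, healthy, cancerous)
    g_inf = 1.0 - D.sum(axis=1)

    dt = protocol.dt
    efac = np.exp(-dt / tau)                       # (n_el, m)
    alpha = tau / dt * (1.0 - efac)
    gamma = g_inf + (D * alpha).sum(axis=1)        # effective step stiffness factor

    # Dirichlet sets: top edge y prescribed, bottom edge y fixed, one x pin
    top_nodes = np.arange(ny * (nx + 1), (ny + 1) * (nx + 1))
    bot_nodes = np.arange(0, nx + 1)
    top_ydofs = 2 * top_nodes + 1
    bot_ydofs = 2 * bot_nodes + 1
    pin = np.array([0])                            # u_x of bottom-left corner
    fixed = np.concatenate([top_ydofs, bot_ydofs, pin])
    if np.unique(fixed).size != fixed.size:
        raise BoundaryConditionError("overlapping constraint sets")
    fixed_mask = np.zeros(ndof, dtype=bool)
    fixed_mask[fixed] = True
    free = np.nonzero(~fixed_mask)[0]

    def assemble(scale):
        data = np.einsum("n,ij->nij", scale, K_unit).ravel()
        rows = np.repeat(edofs, 8, axis=1).ravel()
        cols = np.tile(edofs, (1, 8)).ravel()
        return sp.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsc()

    K = assemble(E0 * gamma)
    K_ff = K[free][:, free]
    K_fc = K[free][:, fixed]
    try:
        lu = splu(K_ff)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise BoundaryConditionError(f"singular stiffness: {exc}") from exc

    t_end = protocol.ramp_time + protocol.hold_time
    times = np.arange(0.0, t_end + 0.5 * dt, dt)

    def platen_disp(t):
        if protocol.ramp_time == 0:
            return protocol.magnitude
        return protocol.magnitude * min(t / protocol.ramp_time, 1.0)

    n_el = nx * ny
    eps = np.zeros((n_el, 4, 3))
    hvar = np.zeros((n_el, 4, D.shape[1], 3))
    forces = np.zeros_like(times)
    u = np.zeros(ndof)

    def element_strains(u_vec):
        ue = u_vec[edofs]                          # (n_el, 8)
        return np.einsum("gce,ne->ngc", Bs, ue)

    def reaction(sig):
        fe = detJ * np.einsum("gce,ngc->ne", Bs, sig)   # (n_el, 8)
        f_int = np.zeros(ndof)
        np.add.at(f_int, edofs, fe)
        return -float(f_int[top_ydofs].sum())      # compression positive

    def stress_now(eps_now, hvar_now):
        b = g_inf[:, None, None] * eps_now + np.einsum("nm,ngmc->ngc", D, hvar_now)
        return E0[:, None, None] * (b @ C.T)

    start = 1
    if protocol.ramp_time == 0:
        # ideal step: elastic solve at t=0+, internal variables fully loaded
        K0 = assemble(E0)
        lu0 = splu(K0[free][:, free])
        uc = np.zeros(fixed.size)
        uc[: top_ydofs.size] = -protocol.magnitude
        u[fixed] = uc
        u[free] = lu0.solve(-(K0[free][:, fixed] @ uc))
        eps = element_strains(u)
        hvar = np.repeat(eps[:, :, None, :], D.shape[1], axis=2)
        forces[0] = reaction(stress_now(eps, hvar))

    for k in range(start, times.size):
        uc = np.zeros(fixed.size)
        uc[: top_ydofs.size] = -platen_disp(times[k])
        # history load from internal variables and previous strain
        a = np.einsum("nm,ngmc->ngc", D * efac, hvar) \
            - (D * alpha).sum(axis=1)[:, None, None] * eps
        sig_hist = E0[:, None, None] * (a @ C.T)
        fe = detJ * np.einsum("gce,ngc->ne", Bs, sig_hist)
        f_hist = np.zeros(ndof)
        np.add.at(f_hist, edofs, fe)
        rhs = -f_hist[free] - K_fc @ uc
        u[free] = lu.solve(rhs)
        u[fixed] = uc
        eps_new = element_strains(u)
        hvar = efac[:, None, :, None] * hvar \
            + alpha[:, None, :, None] * (eps_new - eps)[:, :, None, :]
        eps = eps_new
        forces[k] = reaction(stress_now(eps, hvar))

    return ResponseTrace(times=times, values=forces, mode="relaxation",
                         ramp_time=protocol.ramp_time)


# --- parametric suite -------------------------------------------------------


@dataclass
class SuiteConfig:
    """Enumeration of a parametric virtual-palpation study.

    ``pairs`` lists (healthy, cancerous) material pairs; the cross product
    pairs x fractions x t_exps x seeds is simulated.  ``indent_strain`` sets
    the platen displacement as a fraction of the sample height.
    """

    pairs: Sequence[tuple[PronyMaterial, PronyMaterial]]
    fractions: Sequence[float]
    t_exps: Sequence[float]
    seeds: Sequence[int]
    nx: int = 40
    ny: int = 40
    element_size: float = 5e-4
    dt: float = 0.05
    ramp_time: float = 1.0
    indent_strain: float = 0.05
    rule_fraction_step: float = 0.01
    nu: float = 0.45
    indented_edge: str = "posterior"


def run_parametric_suite(config: SuiteConfig) -> pd.DataFrame:
    """Simulate, characterize and invert every cell of the suite.

    Returns a tidy table with one row per (pair, fraction, t_exp, seed):
    constituent parameters, realized fraction, fitted (D, tau), estimated
    fraction and signed error.  Per-cell failures are recorded in the
    ``status`` column and do not stop the suite.
    """
    from .homogenize import default_fraction_grid

    grid = default_fraction_grid(config.rule_fraction_step)
    rows = []
    for healthy, cancerous in config.pairs:
        for t_exp in config.t_exps:
            rule_protocol = LoadProtocol(mode="creep", magnitude=1.0,
                                         ramp_time=0.0, hold_time=t_exp,
                                         dt=config.dt)
            rule = get_or_build_rule(healthy, cancerous, rule_protocol, grid,
                                     dt=config.dt)
            magnitude = config.indent_strain * config.ny * config.element_size
            sim_protocol = LoadProtocol(mode="relaxation", magnitude=magnitude,
                                        ramp_time=config.ramp_time,
                                        hold_time=t_exp, dt=config.dt)
            for fraction in config.fractions:
                for seed in config.seeds:
                    row = {
                        "healthy": healthy.name or "healthy",
                        "cancerous": cancerous.name or "cancerous",
                        "E_h_Pa": healthy.E0, "E_c_Pa": cancerous.E0,
                        "tau_h_s": float(healthy.relaxation_times[0]),
                        "tau_c_s": float(cancerous.relaxation_times[0]),
                        "t_exp_s": t_exp, "target_fraction": fraction,
                        "seed": seed,
                    }
                    try:
                        micro = generate_random_microstructure(
                            config.nx, config.ny, fraction, seed,
                            config.element_size)
                        trace = simulate_relaxation(
                            micro, healthy, cancerous, sim_protocol,
                            PalpationBC(indented_edge=config.indented_edge),
                            nu=config.nu)
                        fit = fit_prony_1term(trace)
                        est = estimate_fraction(fit.tau_hm, rule)
                        row.update({
                            "realized_fraction": micro.realized_fraction,
                            "fitted_tau_s": fit.tau_hm,
                            "fitted_D": fit.D_hm,
                            "estimated_fraction": est.fraction,
                            "error": est.fraction - micro.realized_fraction,
                            "clamped": est.clamped,
                            "status": "ok",
                        })
                    except Exception as exc:  # noqa: BLE001 - suite must continue
                        row.update({
                            "realized_fraction": np.nan, "fitted_tau_s": np.nan,
                            "fitted_D": np.nan, "estimated_fraction": np.nan,
                            "error": np.nan, "clamped": False,
                            "status": f"failed: {exc}",
                        })
                    rows.append(row)
    return pd.DataFrame(rows)
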