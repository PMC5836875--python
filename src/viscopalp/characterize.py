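"""Trace characterization and tumor-fraction inversion.

Workflow: a creep or stress-relaxation trace (measured or simulated) is
fitted with a single-term Prony law over its hold window; the fitted apparent
relaxation time tau is then looked up in a tabulated rule of mixtures to
estimate the cancerous-tissue fraction.

The fit normalizes the hold-window signal by its value at hold start and
re-zeroes the clock there, so only (D, tau) are identified — the geometry- and
load-dependent scale drops out, and tau is the sole diagnostic index.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .homogenize import (
    ApparentFit,
    MixtureRule,
    _XCLIP,
    build_mixture_rule,
)
from .materials import LoadProtocol, PronyMaterial

__all__ = [
    "ResponseTrace",
    "FractionEstimate",
    "TraceParseError",
    "AmbiguousRuleError",
    "fit_prony_1term",
    "estimate_fraction",
    "run_diagnosis",
    "read_trace_csv",
    "write_trace_csv",
]

# below this relative decay over the hold window tau is not identifiable
_FLAT_TOL = 1e-4


class TraceParseError(ValueError):
    """A trace file failed to parse; the message carries the line number."""


class AmbiguousRuleError(ValueError):
    """The rule's tau column is non-monotone beyond tolerance: the inverse is
    multi-valued.  ``candidates`` lists the candidate fractions."""

    def __init__(self, msg: str, candidates):
        super().__init__(msg)
        self.candidates = list(candidates)


@dataclass(frozen=True)
class ResponseTrace:
    """Sampled response of a creep (displacement, m) or relaxation (force, N) test."""

    times: np.ndarray
    values: np.ndarray
    mode: Literal["creep", "relaxation"]
    ramp_time: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(times < 0):
            raise ValueError("trace times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        if self.mode not in ("creep", "relaxation"):
            raise ValueError(f"mode must be 'creep' or 'relaxation', got {self.mode!r}")
        if self.ramp_time < 0:
            raise ValueError("ramp_time must be non-negative")
        if self.hold_mask().sum() < 10:
            raise ValueError("need at least 10 samples in the hold window")

    def hold_mask(self) -> np.ndarray:
        return self.times >= self.ramp_time - 1e-12


@dataclass(frozen=True)
class FractionEstimate:
    """Estimated cancerous fraction with its provenance.

    ``clamped`` is set iff the apparent tau fell outside the rule's tau range
    and the fraction was clamped to 0 or 1.  ``fit`` carries the trace fit
    that produced ``apparent_tau`` when the estimate came from run_diagnosis.
    """

    fraction: float
    apparent_tau: float
    clamped: bool
    rule_id: str
    fit: ApparentFit | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if not self.apparent_tau > 0:
            raise ValueError("apparent_tau must be positive")

    def to_dict(self) -> dict:
        d = {
            "fraction": self.fraction,
            "apparent_tau_s": self.apparent_tau,
            "clamped": self.clamped,
            "rule_id": self.rule_id,
        }
        if self.fit is not None:
            d["trace_fit"] = self.fit.to_dict()
        return d


def _prony_decay(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Scaled 1-term decay s*(1 - D(1 - e^{-t/tau})) in transformed params.

    The free amplitude ``s`` (x[2], log-transformed) absorbs measurement
    noise on the single hold-start sample used for normalization; without it
    that one noisy value would bias every residual coherently.
    """
    D = expit(np.clip(x[0], -_XCLIP, _XCLIP))
    tau = np.exp(x[1])
    s = np.exp(x[2])
    return s * (1.0 - D * (1.0 - np.exp(-t / tau)))


def fit_prony_1term(
    trace: ResponseTrace,
    *,
    area: float | None = None,
    strain: float | None = None,
) -> ApparentFit:
    """Least-squares 1-term Prony fit of the normalized hold-window signal.

    Relaxation traces are fitted to s*(1 - D(1 - exp(-t/tau))); creep traces
    to the quasi-elastic compliance analogue.  The clock is re-zeroed at hold
    start and the signal normalized by its value there; the free amplitude s
    (~1) keeps noise on that single normalizing sample from biasing the fit.
    When ``area`` and ``strain`` are given for a relaxation trace, the
    instantaneous modulus is recovered from the hold-start force as
    E0 = F(0) / (A * strain); otherwise ``E_hm`` is None.

    A trace with relative decay below 1e-4 gets D ~ 0 and the
    ``tau_unidentifiable`` flag instead of an error; a trace whose trend is
    non-monotone beyond its noise level gets a ``non_monotone`` warning flag.
    """
    m = trace.hold_mask()
    t = trace.times[m] - trace.times[m][0]
    y = trace.values[m]
    y0 = y[0]
    if y0 == 0:
        raise ValueError("hold-start value is zero; cannot normalize")
    g = y / y0
    if trace.mode == "creep":
        g = 1.0 / g  # creep compliance grows; convert to a decaying signal

    flags: list[str] = []
    span = float(g.max() - g.min())
    if span < _FLAT_TOL:
        # flat trace: no measurable relaxation
        D = 1e-9
        tau = max(t[-1], 1.0)
        E0 = _instantaneous_modulus(trace, y0, area, strain)
        return ApparentFit(E_hm=E0, D_hm=D, tau_hm=tau,
                           objective=float(np.sum((g - 1.0) ** 2)),
                           converged=True, flags=("tau_unidentifiable",))

    # non-monotone beyond noise: compare trend violations with residual scale
    dg = np.diff(g)
    rises = float(np.clip(dg, 0, None).sum())
    if rises > 0.05 * span:
        flags.append("non_monotone")

    D0 = float(np.clip(1.0 - g[-1], 1e-3, 1.0 - 1e-3))
    # crude half-decay time as tau start
    half = g[0] - 0.5 * span
    idx = np.argmax(g <= half)
    tau0 = float(t[idx]) if t[idx] > 0 else float(t[-1] / 4 + t[1])
    x0 = np.array([logit(D0), np.log(tau0), 0.0])

    def residuals(x):
        return _prony_decay(x, t) - g

    res = least_squares(residuals, x0, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
    D = float(expit(np.clip(res.x[0], -_XCLIP, _XCLIP)))
    tau = float(np.exp(res.x[1]))
    scale = float(np.exp(res.x[2]))
    E0 = _instantaneous_modulus(trace, scale * y0, area, strain)
    return ApparentFit(E_hm=E0, D_hm=D, tau_hm=tau,
                       objective=float(np.sum(res.fun**2)),
                       converged=res.status > 0, n_restarts_used=1,
                       flags=tuple(flags))


def _instantaneous_modulus(trace, y0, area, strain):
    if area is None or strain is None:
        return None
    if trace.mode == "relaxation":
        return abs(y0) / (area * strain)
    return None  # creep E0 recovery needs the full force/geometry chain


def estimate_fraction(apparent_tau: float, rule: MixtureRule,
                      *, ambiguity_tol: float = 0.01) -> FractionEstimate:
    """Invert the rule's l_c -> tau_hm table at the measured apparent tau.

    Piecewise-linear interpolation on the monotone envelope of the tau
    column.  A tau outside the rule's range clamps to fraction 0 or 1 with
    the ``clamped`` flag.  If the tau column is non-monotone by more than
    ``ambiguity_tol`` times its range, the inverse is multi-valued and an
    :class:`AmbiguousRuleError` listing candidate fractions is raised.
    """
    tau = np.asarray(rule.tau_values, dtype=float)
    frac = rule.fractions
    increasing = tau[-1] >= tau[0]
    s = tau if increasing else -tau
    env = np.maximum.accumulate(s)
    violation = float(np.max(env - s))
    span = float(s.max() - s.min())
    if span > 0 and violation > ambiguity_tol * span:
        x = float(apparent_tau) if increasing else -float(apparent_tau)
        hits = np.nonzero((s[:-1] - x) * (s[1:] - x) <= 0)[0]
        cands = []
        for i in hits:
            if s[i + 1] != s[i]:
                w = (x - s[i]) / (s[i + 1] - s[i])
            else:
                w = 0.5
            cands.append(float(frac[i] + w * (frac[i + 1] - frac[i])))
        raise AmbiguousRuleError(
            f"rule tau column non-monotone (violation {violation:.3g} exceeds "
            f"{ambiguity_tol:.3g} of range); candidate fractions {cands}",
            cands,
        )
    x = float(apparent_tau) if increasing else -float(apparent_tau)
    clamped = x < env[0] - 1e-12 or x > env[-1] + 1e-12
    f = float(np.interp(x, env, frac))
    return FractionEstimate(fraction=f, apparent_tau=float(apparent_tau),
                            clamped=bool(clamped), rule_id=rule.content_hash())


# --- rule cache -------------------------------------------------------------

_RULE_CACHE: dict[str, MixtureRule] = {}


def _cache_key(healthy, cancerous, protocol, grid, dt) -> str:
    import hashlib

    payload = {
        "healthy": healthy.to_dict(),
        "cancerous": cancerous.to_dict(),
        "protocol": protocol.to_dict(),
        "fractions": [round(float(f), 12) for f in np.asarray(grid, float)],
        "dt_integration": dt,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def get_or_build_rule(
    healthy: PronyMaterial,
    cancerous: PronyMaterial,
    protocol: LoadProtocol,
    fraction_grid=None,
    *,
    dt: float | None = None,
    cache: bool = True,
) -> MixtureRule:
    """Build a mixture rule, memoized on (materials, protocol, grid, dt)."""
    from .homogenize import default_fraction_grid

    grid = default_fraction_grid() if fraction_grid is None else fraction_grid
    dt_i = protocol.dt if dt is None else dt
    key = _cache_key(healthy, cancerous, protocol, grid, dt_i)
    if cache and key in _RULE_CACHE:
        return _RULE_CACHE[key]
    rule = build_mixture_rule(healthy, cancerous, protocol, grid, dt=dt_i)
    if cache:
        _RULE_CACHE[key] = rule
    return rule


def run_diagnosis(
    trace: ResponseTrace,
    healthy: PronyMaterial,
    cancerous: PronyMaterial,
    protocol: LoadProtocol,
    *,
    rule: MixtureRule | None = None,
    cache: bool = True,
) -> FractionEstimate:
    """Full diagnosis: fit the trace, build (or reuse) the rule, invert.

    The rule is always built from the creep form of the mismatch functional
    over the protocol's hold window with an ideal step load, matching how the
    rule of mixtures is defined; the trace itself may be either test mode.
    Returns a :class:`FractionEstimate` whose ``fit`` field carries the trace
    fit (residual norm, convergence, flags) so no fraction is ever reported
    without its convergence record.
    """
    fit = fit_prony_1term(trace)
    if rule is None:
        rule_protocol = LoadProtocol(mode="creep", magnitude=1.0, ramp_time=0.0,
                                     hold_time=protocol.hold_time, dt=protocol.dt)
        rule = get_or_build_rule(healthy, cancerous, rule_protocol, cache=cache)
    est = estimate_fraction(fit.tau_hm, rule)
    return FractionEstimate(fraction=est.fraction, apparent_tau=est.apparent_tau,
                            clamped=est.clamped, rule_id=est.rule_id, fit=fit)


# --- trace file IO ----------------------------------------------------------

_TRACE_HEADER = ("time_s", "value")


def write_trace_csv(trace: ResponseTrace, path) -> None:
    """Write the two-column trace dialect: header ``time_s,value``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRACE_HEADER)
        for t, v in zip(trace.times, trace.values):
            w.writerow([repr(float(t)), repr(float(v))])


def read_trace_csv(path, mode: str, ramp_time: float = 0.0) -> ResponseTrace:
    """Read a two-column ``time_s,value`` CSV into a ResponseTrace.

    Malformed rows raise :class:`TraceParseError` naming the offending line.
    """
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1:
                if tuple(p.lower() for p in parts) != _TRACE_HEADER:
                    raise TraceParseError(
                        f"{path}: line 1: expected header 'time_s,value', "
                        f"got {line!r}"
                    )
                continue
            if len(parts) != 2:
                raise TraceParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise TraceParseError(
                    f"{path}: line {lineno}: non-numeric entry ({exc})"
                ) from None
    return ResponseTrace(times=np.array(times), values=np.array(values),
                         mode=mode, ramp_time=ramp_time)
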