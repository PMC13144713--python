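"""Diffusion-decision model (DDM) numerics.

The DDM describes a two-choice decision as a noisy accumulation of relative
evidence between two absorbing boundaries.  Under accuracy coding the upper
boundary is the correct response and the lower boundary the error; the
accumulator starts at a fraction ``z`` of the boundary separation ``a``,
drifts at mean rate ``v`` (diffusion coefficient fixed at 1), and the
observed response time adds a non-decision time ``t0`` for encoding and
motor execution.  Across-trial variabilities ``sv`` (normal SD of drift),
``sz`` (uniform range of the relative start) and ``st0`` (uniform range of
non-decision time) are supported throughout.

This module exposes the first-passage density (the likelihood kernel), the
closed-form choice probability and mean decision time (used as test
oracles), a seeded trial simulator, and the trial-set log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from . import _wfpt

DEFAULT_EPS = 1e-7
DEFAULT_QUAD_NODES = 11
DEFAULT_SIM_DT = 1e-4

__all__ = [
    "DDMParams",
    "TrialOutcome",
    "SimulatedTrials",
    "DDMValidationError",
    "UnsupportedCaseError",
    "wfpt_density",
    "choice_probability",
    "mean_decision_time",
    "simulate_trials",
    "log_likelihood",
]


class DDMValidationError(ValueError):
    """Raised when parameters or inputs violate a model invariant."""


class UnsupportedCaseError(ValueError):
    """Raised when a closed form is requested outside its validity region."""


@dataclass(frozen=True)
class DDMParams:
    """One subject's decision parameters.

    v : drift rate (evidence units / s), toward the correct boundary
    a : boundary separation (evidence units), > 0
    z : relative starting point in (0, 1) as a fraction of ``a``
    t0 : non-decision time (s), >= 0
    sv : across-trial SD of drift, >= 0
    sz : across-trial uniform range of the relative start, >= 0
    st0 : across-trial uniform range of non-decision time (s), >= 0
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.3
    sv: float = 0.0
    sz: float = 0.0
    st0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not all(np.isfinite([self.v, self.a, self.z, self.t0, self.sv, self.sz, self.st0])):
            raise DDMValidationError("all parameters must be finite")
        if self.a <= 0:
            raise DDMValidationError(f"boundary separation must satisfy a > 0, got a={self.a}")
        if not 0.0 < self.z < 1.0:
            raise DDMValidationError(f"relative start must satisfy 0 < z < 1, got z={self.z}")
        if self.t0 < 0:
            raise DDMValidationError(f"non-decision time must satisfy t0 >= 0, got t0={self.t0}")
        if self.sv < 0 or self.sz < 0 or self.st0 < 0:
            raise DDMValidationError("variabilities sv, sz, st0 must be >= 0")
        if self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= 1:
            raise DDMValidationError(
                f"start range must stay inside the boundaries: z +/- sz/2 in (0, 1), "
                f"got z={self.z}, sz={self.sz}"
            )
        if self.t0 - self.st0 / 2 < 0:
            raise DDMValidationError(
                f"non-decision time range must stay non-negative: t0 - st0/2 >= 0, "
                f"got t0={self.t0}, st0={self.st0}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.a, self.z, self.t0, self.sv, self.sz, self.st0])

    @staticmethod
    def names() -> list[str]:
        return ["v", "a", "z", "t0", "sv", "sz", "st0"]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "DDMParams":
        return cls(*[float(x) for x in arr])


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated trial: terminating boundary, rt (s), omission flag."""

    correct: Optional[bool]
    rt: Optional[float]
    omitted: bool = False


@dataclass
class SimulatedTrials:
    """Vectorised container of simulated trials.

    ``correct`` is -1 on omitted trials, which carry ``rt = nan``.
    """

    rt: np.ndarray
    correct: np.ndarray
    omitted: np.ndarray
    seed: int = field(default=0)

    def __len__(self) -> int:
        return len(self.rt)

    def __iter__(self) -> Iterator[TrialOutcome]:
        for r, c, o in zip(self.rt, self.correct, self.omitted):
            if o:
                yield TrialOutcome(correct=None, rt=None, omitted=True)
            else:
                yield TrialOutcome(correct=bool(c), rt=float(r), omitted=False)

    @property
    def completed(self) -> "SimulatedTrials":
        keep = self.omitted == 0
        return SimulatedTrials(self.rt[keep], self.correct[keep],
                               self.omitted[keep], self.seed)


def _quad(params: DDMParams, n_nodes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nw, ww = _wfpt.gauss_legendre_nodes(n_nodes if params.sz > 0 else 1)
    nt, wt = _wfpt.gauss_legendre_nodes(n_nodes if params.st0 > 0 else 1)
    return nw, ww, nt, wt


def wfpt_density(
    t,
    boundary: str,
    params: DDMParams,
    eps: float = DEFAULT_EPS,
    n_quad: int = DEFAULT_QUAD_NODES,
):
    """First-passage density (per second) at response time ``t``.

    ``boundary`` is ``"correct"`` (upper) or ``"error"`` (lower).  Accepts a
    scalar or an array of times; times at or before the earliest possible
    non-decision time have zero density.
    """
    params.validate()
    if boundary not in ("correct", "error"):
        raise DDMValidationError(f"boundary must be 'correct' or 'error', got {boundary!r}")
    upper = boundary == "correct"
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(ts)):
        raise DDMValidationError("t must be finite")
    nw, ww, nt, wt = _quad(params, n_quad)
    out = _wfpt.density_array(ts, upper, params.v, params.a, params.z, params.t0,
                              params.sv, params.sz, params.st0, eps, nw, ww, nt, wt)
    return float(out[0]) if np.isscalar(t) else out


def _p_upper(v: float, a: float, z: float) -> float:
    # absorption probability at the upper boundary for drifted Brownian motion
    if abs(v) < 1e-8:
        return z
    x = -2.0 * v * a * z
    y = -2.0 * v * a
    # (1 - e^x) / (1 - e^y), stable via expm1
    return math.expm1(x) / math.expm1(y)


def choice_probability(
    params: DDMParams,
    n_quad: int = DEFAULT_QUAD_NODES,
    n_hermite: int = 31,
) -> float:
    """Probability of terminating at the correct (upper) boundary.

    Closed form for fixed drift/start; with sv or sz > 0 the closed form is
    averaged numerically (Gauss-Hermite over drift, Gauss-Legendre over the
    start point).  st0 does not affect the choice.
    """
    params.validate()
    if params.sv > 0:
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_hermite)
        vs = params.v + params.sv * gh_x
        vw = gh_w / gh_w.sum()
    else:
        vs, vw = np.array([params.v]), np.array([1.0])
    if params.sz > 0:
        zn, zw = _wfpt.gauss_legendre_nodes(n_quad)
        zs = params.z + params.sz * zn
    else:
        zs, zw = np.array([params.z]), np.array([1.0])
    p = 0.0
    for vi, wv in zip(vs, vw):
        for zi, wz in zip(zs, zw):
            p += wv * wz * _p_upper(vi, params.a, zi)
    return float(p)


def mean_decision_time(params: DDMParams) -> float:
    """Mean decision time (s), marginal over boundaries.

    Closed form for the mean first-exit time of drifted Brownian motion from
    (0, a); only defined for sv = sz = 0 (st0 does not enter the decision
    stage).  Continuous in v at v = 0, where it reduces to z_abs (a - z_abs).
    """
    params.validate()
    if params.sv > 0 or params.sz > 0:
        raise UnsupportedCaseError(
            "mean_decision_time has a closed form only for sv = sz = 0; "
            "use simulate_trials for variability-averaged summaries"
        )
    x0 = params.z * params.a
    v, a = params.v, params.a
    if abs(v * a) < 1e-6:
        return x0 * (a - x0)
    return (a * (-math.expm1(-2.0 * v * x0)) / (-math.expm1(-2.0 * v * a)) - x0) / v


def simulate_trials(
    params: DDMParams,
    n: int,
    deadline: Optional[float] = None,
    seed: int = 0,
    dt: float = DEFAULT_SIM_DT,
) -> SimulatedTrials:
    """Simulate ``n`` trials by Euler-Maruyama with step ``dt`` (s).

    Trials whose response would land after ``deadline`` (s from stimulus
    onset) are flagged omitted.  Identical seeds give bit-identical output.
    """
    params.validate()
    if n < 1:
        raise DDMValidationError(f"n must be >= 1, got {n}")
    if deadline is not None and deadline <= params.t0 - params.st0 / 2:
        raise DDMValidationError("deadline must exceed the earliest non-decision time")
    dl = float(deadline) if deadline is not None else -1.0
    rt, correct, omitted = _wfpt.simulate(
        int(n), params.v, params.a, params.z, params.t0,
        params.sv, params.sz, params.st0, dt, dl, int(seed))
    return SimulatedTrials(rt=rt, correct=correct, omitted=omitted, seed=int(seed))


def log_likelihood(
    rt: np.ndarray,
    correct: np.ndarray,
    params: DDMParams,
    eps: float = DEFAULT_EPS,
    n_quad: int = DEFAULT_QUAD_NODES,
) -> float:
    """Sum of log first-passage densities over cleaned trials.

    ``rt`` in seconds; ``correct`` boolean (or 0/1).  Empty input returns 0
    (empty-sum convention).  A trial with rt at or below ``t0 - st0/2`` makes
    the result -inf; this is a documented contract, not an exception.
    """
    params.validate()
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct).astype(np.int8)
    if rt.size == 0:
        return 0.0
    if np.any(~np.isfinite(rt)):
        raise DDMValidationError("rt values must be finite (drop omissions first)")
    nw, ww, nt, wt = _quad(params, n_quad)
    return float(_wfpt.loglike(rt, correct, params.v, params.a, params.z, params.t0,
                               params.sv, params.sz, params.st0, eps, nw, ww, nt, wt))
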