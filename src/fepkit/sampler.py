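"""Analytic-potential Metropolis sampler with known free-energy ground truth.

This module stands in for the MD engine: it samples lambda-coupled analytic
potentials (harmonic wells, double wells, a soft-core pair interaction) with
Metropolis Monte Carlo and records the per-window energy differences that
the estimators consume.  For harmonic systems the free-energy difference has
the closed form

    dG = sum_dims (kT/2) * ln(k_B / k_A)

(independent of the well centers), which makes these systems exact
validation oracles for the whole estimation pipeline.

Sampling follows the sequential lambda protocol: each window starts from the
previous window's endpoint, discards a burn-in fraction, then records the
energy difference to the next lambda (forward) and to the previous lambda
(backward).  Replica ``r`` uses seed ``seed + r`` so fixtures are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ComputationError, ValidationError
from .estimators import ReplicaSeries, WindowSamples

__all__ = ["PotentialSpec", "CoupledHamiltonian", "SamplerConfig",
           "metropolis_sample", "analytic_dg", "softcore_energy",
           "generate_gaussian_samples"]

_FAMILIES = ("harmonic", "double_well", "softcore_pair")


@dataclass(frozen=True)
class PotentialSpec:
    """An analytic potential.

    families and parameters (energies kcal/mol, lengths angstrom):

    * ``harmonic`` — ``k`` (force constant, scalar or per-dimension list),
      ``center`` (scalar or per-dimension list).
    * ``double_well`` — ``height`` (barrier, kcal/mol), ``separation``
      (distance between minima); 1-D per dimension.
    * ``softcore_pair`` — ``eps``, ``sigma``, ``alpha``, ``lam`` (soft-core
      progress variable; 0 = plain Lennard-Jones, 1 = annihilated).  The
      coordinate is the pair separation vector.
    """

    family: str
    parameters: dict
    dimensionality: int = 1

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown potential family {self.family!r}")
        if self.dimensionality < 1:
            raise ValidationError("dimensionality must be positive")
        p = self.parameters
        if self.family == "harmonic":
            if np.any(np.asarray(p["k"], dtype=float) <= 0):
                raise ValidationError("harmonic force constants must be > 0")
        elif self.family == "double_well":
            if p["height"] <= 0 or p["separation"] <= 0:
                raise ValidationError("double-well parameters must be > 0")
        else:
            if p["eps"] <= 0 or p["sigma"] <= 0:
                raise ValidationError("eps and sigma must be > 0")
            if p.get("alpha", 0.5) < 0:
                raise ValidationError("alpha must be >= 0")

    def _vec(self, name: str, default=None) -> np.ndarray:
        v = self.parameters.get(name, default)
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.dimensionality, float(arr))
        if arr.size != self.dimensionality:
            raise ValidationError(
                f"parameter {name!r} has {arr.size} entries for "
                f"{self.dimensionality} dimensions")
        return arr

    def energy(self, x: np.ndarray) -> np.ndarray | float:
        """Potential energy; ``x`` has shape (..., d), result shape (...)."""
        x = np.asarray(x, dtype=float)
        if self.family == "harmonic":
            k = self._vec("k")
            c = self._vec("center", 0.0)
            return 0.5 * np.sum(k * (x - c) ** 2, axis=-1)
        if self.family == "double_well":
            h = float(self.parameters["height"])
            a = float(self.parameters["separation"])
            return np.sum(h * ((2.0 * x / a) ** 2 - 1.0) ** 2, axis=-1)
        p = self.parameters
        r = np.sqrt(np.sum(x * x, axis=-1))
        return softcore_energy(r, p.get("lam", 0.0), p["eps"], p["sigma"],
                               p.get("alpha", 0.5))

    def start_point(self) -> np.ndarray:
        """A reasonable initial coordinate inside the dominant well."""
        if self.family == "harmonic":
            return self._vec("center", 0.0).copy()
        if self.family == "double_well":
            a = float(self.parameters["separation"])
            return np.full(self.dimensionality, a / 2.0)
        return np.full(self.dimensionality,
                       float(self.parameters["sigma"]) * 2 ** (1 / 6)
                       / math.sqrt(self.dimensionality))


@dataclass(frozen=True)
class CoupledHamiltonian:
    """Two endpoint potentials joined by a lambda coupling.

    ``linear`` coupling interpolates energies, U = (1-lam) U_A + lam U_B.
    ``staged`` coupling interpolates the parameters of same-family endpoints
    (e.g. force constant and center for harmonic wells, the soft-core
    progress variable for pair potentials).  Both reduce exactly to the
    endpoint potentials at lam = 0 and 1.
    """

    endpoint_A: PotentialSpec
    endpoint_B: PotentialSpec
    coupling: str = "linear"

    def __post_init__(self):
        if self.coupling not in ("linear", "staged"):
            raise ValidationError(f"unknown coupling {self.coupling!r}")
        if (self.coupling == "staged"
                and self.endpoint_A.family != self.endpoint_B.family):
            raise ValidationError(
                "staged coupling requires same-family endpoints")
        if self.endpoint_A.dimensionality != self.endpoint_B.dimensionality:
            raise ValidationError("endpoint dimensionalities differ")

    @property
    def dimensionality(self) -> int:
        return self.endpoint_A.dimensionality

    def _staged_spec(self, lam: float) -> PotentialSpec:
        a, b = self.endpoint_A, self.endpoint_B
        mixed = {}
        for name in set(a.parameters) | set(b.parameters):
            va = np.asarray(a.parameters.get(name, b.parameters[name]), float)
            vb = np.asarray(b.parameters.get(name, a.parameters[name]), float)
            v = (1.0 - lam) * va + lam * vb
            mixed[name] = v.tolist() if v.ndim else float(v)
        return PotentialSpec(a.family, mixed, a.dimensionality)

    def potential(self, lam: float):
        """Return a callable U(x) for a fixed lambda."""
        if lam == 0.0:
            return self.endpoint_A.energy
        if lam == 1.0:
            return self.endpoint_B.energy
        if self.coupling == "linear":
            ea, eb = self.endpoint_A.energy, self.endpoint_B.energy
            return lambda x: (1.0 - lam) * ea(x) + lam * eb(x)
        return self._staged_spec(lam).energy

    def energy(self, x, lam: float):
        return self.potential(lam)(x)


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis sampling protocol parameters."""

    n_steps_per_window: int = 10000
    step_size: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    n_replicas: int = 10
    seed: int = 0
    burn_in_fraction: float = 0.1

    def __post_init__(self):
        if (self.n_steps_per_window <= 0 or self.step_size <= 0
                or self.temperature <= 0 or self.n_replicas <= 0):
            raise ValidationError("sampler parameters must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValidationError("burn_in_fraction must be in [0, 1)")


def _quad_coeffs_1d(h: "CoupledHamiltonian", lam: float):
    """(A, B, C) of U = 0.5 A x^2 + B x + C for 1-D harmonic endpoint pairs.

    Exists for both linear coupling (energy mixing of two parabolas stays
    quadratic) and staged coupling (parameter-interpolated parabola); returns
    None when the Hamiltonian is not representable this way.
    """
    a, b = h.endpoint_A, h.endpoint_B
    if (a.family != "harmonic" or b.family != "harmonic"
            or a.dimensionality != 1):
        return None
    ka, ca = float(a._vec("k")[0]), float(a._vec("center", 0.0)[0])
    kb, cb = float(b._vec("k")[0]), float(b._vec("center", 0.0)[0])
    if h.coupling == "staged":
        k = (1.0 - lam) * ka + lam * kb
        c = (1.0 - lam) * ca + lam * cb
        return k, -k * c, 0.5 * k * c * c
    wa, wb = (1.0 - lam) * ka, lam * kb
    return (wa + wb, -(wa * ca + wb * cb),
            0.5 * (wa * ca * ca + wb * cb * cb))


def _run_window_quad1d(coeffs, x: float, n_burn: int, n_record: int,
                       step: float, beta: float, rng: np.random.Generator):
    """Scalar Metropolis walk on U = 0.5 A x^2 + B x + C (fast path)."""
    A, B, _ = coeffs
    total = n_burn + n_record
    props = rng.uniform(-step, step, size=total)
    accept_u = rng.random(total)
    traj = np.empty(n_record)
    u_x = 0.5 * A * x * x + B * x
    exp = math.exp
    for i in range(total):
        xn = x + props[i]
        u_n = 0.5 * A * xn * xn + B * xn
        du = u_n - u_x
        if du <= 0.0 or accept_u[i] < exp(-beta * du):
            x, u_x = xn, u_n
        if i >= n_burn:
            traj[i - n_burn] = x
    return x, traj


def _run_window(pot, x: np.ndarray, n_burn: int, n_record: int,
                step: float, beta: float, rng: np.random.Generator):
    """Metropolis walk at fixed lambda; returns (final x, recorded positions)."""
    d = x.size
    total = n_burn + n_record
    props = rng.uniform(-step, step, size=(total, d))
    accept_u = rng.random(total)
    traj = np.empty((n_record, d))
    u_x = float(pot(x))
    exp = math.exp
    for i in range(total):
        xn = x + props[i]
        u_n = float(pot(xn))
        du = u_n - u_x
        if du <= 0.0 or accept_u[i] < exp(-beta * du):
            x, u_x = xn, u_n
        if i >= n_burn:
            traj[i - n_burn] = x
    return x, traj


def metropolis_sample(h: CoupledHamiltonian, schedule,
                      config: SamplerConfig) -> list[ReplicaSeries]:
    """Sample a lambda schedule and collect forward/backward dU per window.

    For each replica the walker visits the schedule points sequentially;
    at point ``i`` it records dU to point ``i+1`` (the forward samples of
    window ``i``) and dU to point ``i-1`` (the backward samples of window
    ``i-1``).  Returns one tiled :class:`ReplicaSeries` per replica.
    """
    schedule = [float(l) for l in schedule]
    if len(schedule) < 2:
        raise ValidationError("schedule needs at least 2 lambda points")
    beta = 1.0 / kt(config.temperature)
    n_burn = int(config.burn_in_fraction * config.n_steps_per_window)
    pots = [h.potential(l) for l in schedule]
    quads = [_quad_coeffs_1d(h, l) for l in schedule]
    replicas = []
    for r in range(config.n_replicas):
        rng = np.random.default_rng(config.seed + r)
        x = h.endpoint_A.start_point().astype(float)
        fwd = [None] * (len(schedule) - 1)
        bwd = [None] * (len(schedule) - 1)
        for i, pot in enumerate(pots):
            if quads[i] is not None:
                x1, traj1 = _run_window_quad1d(
                    quads[i], float(x[0]), n_burn,
                    config.n_steps_per_window, config.step_size, beta, rng)
                x = np.array([x1])
                traj = traj1[:, None]
            else:
                x, traj = _run_window(pot, x, n_burn,
                                      config.n_steps_per_window,
                                      config.step_size, beta, rng)
            u_here = pot(traj)
            if i + 1 < len(pots):
                fwd[i] = np.asarray(pots[i + 1](traj) - u_here)
            if i > 0:
                bwd[i - 1] = np.asarray(pots[i - 1](traj) - u_here)
        windows = [
            WindowSamples(lambda_from=schedule[i], lambda_to=schedule[i + 1],
                          dU_forward=fwd[i], dU_backward=bwd[i],
                          temperature=config.temperature)
            for i in range(len(schedule) - 1)
        ]
        replicas.append(ReplicaSeries(replica_id=r, windows=windows,
                                      seed=config.seed + r))
    return replicas


def analytic_dg(a: PotentialSpec, b: PotentialSpec,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Closed-form dG between two harmonic potentials (oracle).

    ``sum_dims (kT/2) ln(k_b/k_a)``; independent of the well centers.
    """
    if a.family != "harmonic" or b.family != "harmonic":
        raise ComputationError(
            "analytic free energy is only available for harmonic potentials")
    ka, kb = a._vec("k"), b._vec("k")
    return float(0.5 * kt(temperature) * np.sum(np.log(kb / ka)))


def softcore_energy(r, lam: float, eps: float, sigma: float,
                    alpha: float = 0.5):
    """Soft-core Lennard-Jones interaction.

        U = 4 eps (1-lam) [ (alpha lam + (r/sigma)^6)^-2
                            - (alpha lam + (r/sigma)^6)^-1 ]

    Reduces to plain LJ at lam=0, vanishes at lam=1, and stays finite at
    r=0 whenever alpha*lam > 0.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("lam must be in [0, 1]")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValidationError("r must be non-negative")
    if lam == 1.0:
        return np.zeros_like(r_arr) if r_arr.ndim else 0.0
    s6 = (r_arr / sigma) ** 6
    denom = alpha * lam + s6
    if np.any(denom == 0.0):
        if lam > 0.0 and alpha == 0.0:
            raise ComputationError(
                "soft-core singularity: alpha = 0 with lam > 0 at r = 0")
        with np.errstate(divide="ignore"):
            out = np.where(denom == 0.0, np.inf,
                           4.0 * eps * (1.0 - lam)
                           * (1.0 / np.maximum(denom, 1e-300) ** 2
                              - 1.0 / np.maximum(denom, 1e-300)))
        return float(out) if out.ndim == 0 else out
    out = 4.0 * eps * (1.0 - lam) * (denom ** -2 - denom ** -1)
    return float(out) if out.ndim == 0 else out


def generate_gaussian_samples(mu: float, sigma: float, n: int,
                              temperature: float = DEFAULT_TEMPERATURE,
                              seed: int = 0) -> WindowSamples:
    """Gaussian dU fixture with a closed-form true free energy.

    Forward dU ~ N(mu, sigma^2); the true dG is ``mu - sigma^2/(2 kT)``
    (Gaussian EXP identity).  Backward dU is drawn as
    ``N(sigma^2/kT - mu, sigma^2)`` so the reverse-path EXP estimate shares
    the same true dG with opposite sign.  Seeded and reproducible.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kT = kt(temperature)
    fwd = mu + sigma * rng.standard_normal(n)
    bwd = (sigma * sigma / kT - mu) + sigma * rng.standard_normal(n)
    return WindowSamples(lambda_from=0.0, lambda_to=1.0, dU_forward=fwd,
                         dU_backward=bwd, temperature=temperature)
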