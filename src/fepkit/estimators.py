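"""Free-energy estimation from per-window energy-difference samples.

The core estimator is Zwanzig exponential averaging (EXP):

    dG = -kT * ln < exp(-dU / kT) >

evaluated per lambda-window with a log-sum-exp guard and summed over the
windows of a leg.  Replicas (independent repeats with different initial
velocities/seeds) give the reported leg value as a mean with a standard
error, and the forward/backward discrepancy (hysteresis) serves as a
convergence diagnostic.  A Bennett acceptance ratio (BAR) solver is included
as an independent cross-check estimator.

Conventions
-----------
* ``dU_forward`` is U(lambda_to) - U(lambda_from) sampled on the lambda_from
  ensemble; ``dU_backward`` is the same difference with the roles swapped,
  sampled on the lambda_to ensemble.
* Per replica, ``dG_forward`` is the EXP sum over forward samples and
  ``dG_backward`` the EXP sum for the reverse path, so a converged pair
  satisfies ``dG_forward ~= -dG_backward``.
* The reported replica value is ``(dG_forward - dG_backward) / 2`` and the
  replica hysteresis ``|dG_forward + dG_backward|``.
* s.e.m. uses the sample standard deviation (n-1) over replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ComputationError, ValidationError

__all__ = ["WindowSamples", "ReplicaSeries", "LegEstimate", "zwanzig_window",
           "leg_free_energy", "bar_window", "read_energy_csv",
           "write_energy_csv"]

ENERGY_CSV_COLUMNS = ["replica", "stage", "window_index", "lambda_from",
                      "lambda_to", "direction", "dU_kcal_mol", "temperature_K"]

_TILE_TOL = 1e-9


@dataclass
class WindowSamples:
    """Energy-difference samples for one lambda-window.

    ``dU_forward`` is sampled on the ``lambda_from`` ensemble,
    ``dU_backward`` on the ``lambda_to`` ensemble; either may be empty if
    only one direction is used.  Energies in kcal/mol, temperature in K.
    """

    lambda_from: float
    lambda_to: float
    dU_forward: np.ndarray = field(default_factory=lambda: np.empty(0))
    dU_backward: np.ndarray = field(default_factory=lambda: np.empty(0))
    temperature: float = DEFAULT_TEMPERATURE
    stage: str = "all"

    def __post_init__(self):
        self.dU_forward = np.asarray(self.dU_forward, dtype=float)
        self.dU_backward = np.asarray(self.dU_backward, dtype=float)
        if self.lambda_from == self.lambda_to:
            raise ValidationError(
                f"window has lambda_from == lambda_to == {self.lambda_from}")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.dU_forward.size == 0 and self.dU_backward.size == 0:
            raise ValidationError("window carries no samples in either direction")

    @property
    def key(self) -> tuple:
        return (self.stage, round(self.lambda_from, 12), round(self.lambda_to, 12))


@dataclass
class ReplicaSeries:
    """All windows of one replica, tiling the full schedule of a leg."""

    replica_id: int
    windows: list[WindowSamples]
    seed: int | None = None

    def __post_init__(self):
        if not self.windows:
            raise ValidationError("replica has no windows")
        prev = None
        for w in self.windows:
            if prev is not None and prev.stage == w.stage:
                if abs(prev.lambda_to - w.lambda_from) > _TILE_TOL:
                    raise ValidationError(
                        f"lambda tiling gap in stage {w.stage!r}: window ends "
                        f"at {prev.lambda_to} but next starts at {w.lambda_from}")
            prev = w

    def schedule_key(self) -> tuple:
        return tuple(w.key for w in self.windows)


@dataclass
class LegEstimate:
    """One cycle leg's free energy with replica statistics (kcal/mol)."""

    dG: float
    dG_forward: float
    dG_backward: float
    hysteresis: float
    sem: float
    per_replica_dG: list[float]
    n_replicas: int

    def to_dict(self) -> dict:
        return {
            "dG_kcal_mol": self.dG,
            "dG_forward_kcal_mol": self.dG_forward,
            "dG_backward_kcal_mol": self.dG_backward,
            "hysteresis_kcal_mol": self.hysteresis,
            "sem_kcal_mol": self.sem,
            "per_replica_dG_kcal_mol": list(self.per_replica_dG),
            "n_replicas": self.n_replicas,
            "units": "kcal/mol",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LegEstimate":
        return cls(dG=d["dG_kcal_mol"], dG_forward=d["dG_forward_kcal_mol"],
                   dG_backward=d["dG_backward_kcal_mol"],
                   hysteresis=d["hysteresis_kcal_mol"],
                   sem=d["sem_kcal_mol"],
                   per_replica_dG=list(d["per_replica_dG_kcal_mol"]),
                   n_replicas=d["n_replicas"])


def _check_samples(dU: np.ndarray) -> np.ndarray:
    dU = np.asarray(dU, dtype=float)
    if dU.size == 0:
        raise ValidationError("empty sample set")
    bad = np.flatnonzero(~np.isfinite(dU))
    if bad.size:
        raise ValidationError(
            f"non-finite dU samples at indices {bad[:20].tolist()}")
    return dU


def zwanzig_window(dU, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Zwanzig (EXP) free-energy estimate for one window.

    Returns ``-kT * ln(mean(exp(-dU/kT)))`` computed via log-sum-exp so that
    large |dU| cannot overflow.  ``dU`` in kcal/mol, ``temperature`` in K.
    """
    dU = _check_samples(dU)
    beta = 1.0 / kt(temperature)
    return float(-(logsumexp(-beta * dU) - np.log(dU.size)) / beta)


def leg_free_energy(replicas: list[ReplicaSeries]) -> LegEstimate:
    """Combine replica window samples into a leg estimate.

    Per replica the forward (initial -> target) and backward (target ->
    initial) path free energies are EXP sums over the windows; the replica
    value is their antisymmetrized mean ``(dG_fwd - dG_bwd)/2`` and the
    replica hysteresis ``|dG_fwd + dG_bwd|``.  The leg reports means over
    replicas, with s.e.m. = sd/sqrt(n) (0 for a single replica).
    """
    if not replicas:
        raise ValidationError("need at least one replica")
    key0 = replicas[0].schedule_key()
    for r in replicas[1:]:
        if r.schedule_key() != key0:
            raise ValidationError(
                f"replica {r.replica_id} does not tile the same schedule as "
                f"replica {replicas[0].replica_id}")
    fwd, bwd, per, hyst = [], [], [], []
    for r in replicas:
        f = sum(zwanzig_window(w.dU_forward, w.temperature)
                for w in r.windows if w.dU_forward.size)
        b = sum(zwanzig_window(w.dU_backward, w.temperature)
                for w in r.windows if w.dU_backward.size)
        fwd.append(f)
        bwd.append(b)
        per.append((f - b) / 2.0)
        hyst.append(abs(f + b))
    n = len(per)
    sem = float(np.std(per, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return LegEstimate(
        dG=float(np.mean(per)),
        dG_forward=float(np.mean(fwd)),
        dG_backward=float(np.mean(bwd)),
        hysteresis=float(np.mean(hyst)),
        sem=sem,
        per_replica_dG=[float(x) for x in per],
        n_replicas=n,
    )


def bar_window(dU_forward, dU_backward,
               temperature: float = DEFAULT_TEMPERATURE,
               tol: float = 1e-8) -> float:
    """Bennett acceptance ratio estimate for one window (cross-check oracle).

    Solves the self-consistency condition

        sum_i f(beta*(dU_f_i - dG + M)) = sum_j f(beta*(dU_b_j + dG - M))

    with Fermi function ``f`` and ``M = kT ln(n_f/n_b)``, by bracketing and
    Brent root finding to tolerance ``tol``.
    """
    dU_f = _check_samples(dU_forward)
    dU_b = _check_samples(dU_backward)
    kT = kt(temperature)
    beta = 1.0 / kT
    M = kT * np.log(dU_f.size / dU_b.size)

    def fermi_sum(x):
        # sum of 1/(1+exp(x)); clip keeps exp() finite, limits are exact 0/1
        return np.sum(1.0 / (1.0 + np.exp(np.clip(x, -700, 700))))

    def g(dg):
        lhs = fermi_sum(beta * (dU_f - dg + M))
        rhs = fermi_sum(beta * (dU_b + dg - M))
        return lhs - rhs

    # g is increasing in dg; expand a bracket around the EXP estimate
    center = zwanzig_window(dU_f, temperature)
    half = max(1.0, np.ptp(dU_f) + np.ptp(dU_b))
    lo, hi = center - half, center + half
    for _ in range(60):
        if g(lo) < 0 < g(hi):
            break
        if g(lo) >= 0:
            lo -= half
        if g(hi) <= 0:
            hi += half
        half *= 2
    else:
        raise ComputationError("no bracketing interval found for BAR")
    return float(brentq(g, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# energy-sample CSV dialect


def write_energy_csv(replicas: list[ReplicaSeries], path: str | Path) -> None:
    """Write replicas in the long-format energy CSV dialect (one sample/row)."""
    rows = []
    for r in replicas:
        for i, w in enumerate(r.windows):
            for direction, dU in (("fwd", w.dU_forward), ("bwd", w.dU_backward)):
                for x in dU:
                    rows.append((r.replica_id, w.stage, i, w.lambda_from,
                                 w.lambda_to, direction, x, w.temperature))
    df = pd.DataFrame(rows, columns=ENERGY_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_energy_csv(path: str | Path) -> list[ReplicaSeries]:
    """Parse the energy CSV dialect into :class:`ReplicaSeries`.

    Expected columns: ``replica, stage, window_index, lambda_from,
    lambda_to, direction (fwd|bwd), dU_kcal_mol, temperature_K``.  Windows
    must tile lambda within each stage; temperatures must be uniform within
    a window.
    """
    df = pd.read_csv(path)
    missing = [c for c in ENERGY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"energy CSV is missing columns: {missing}")
    bad_dir = set(df["direction"].unique()) - {"fwd", "bwd"}
    if bad_dir:
        raise ValidationError(f"unknown direction values: {sorted(bad_dir)}")
    replicas = []
    for rid, rdf in df.groupby("replica", sort=True):
        windows = []
        # preserve file order of stages, numeric order of windows
        stage_order = {s: i for i, s in enumerate(dict.fromkeys(rdf["stage"]))}
        keys = sorted(set(zip(rdf["stage"], rdf["window_index"])),
                      key=lambda k: (stage_order[k[0]], k[1]))
        for stage, widx in keys:
            wdf = rdf[(rdf["stage"] == stage) & (rdf["window_index"] == widx)]
            for col in ("lambda_from", "lambda_to"):
                if wdf[col].nunique() > 1:
                    raise ValidationError(
                        f"inconsistent {col} within replica {rid}, "
                        f"stage {stage!r}, window {widx}")
            if wdf["temperature_K"].nunique() > 1:
                raise ValidationError(
                    f"mixed temperatures within replica {rid}, "
                    f"stage {stage!r}, window {widx}")
            windows.append(WindowSamples(
                lambda_from=float(wdf["lambda_from"].iloc[0]),
                lambda_to=float(wdf["lambda_to"].iloc[0]),
                dU_forward=wdf.loc[wdf["direction"] == "fwd",
                                   "dU_kcal_mol"].to_numpy(),
                dU_backward=wdf.loc[wdf["direction"] == "bwd",
                                    "dU_kcal_mol"].to_numpy(),
                temperature=float(wdf["temperature_K"].iloc[0]),
                stage=str(stage),
            ))
        replicas.append(ReplicaSeries(replica_id=int(rid), windows=windows))
    return replicas
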