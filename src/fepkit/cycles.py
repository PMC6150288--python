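"""Thermodynamic-cycle algebra for relative binding free energies.

A computable alchemical leg (a transformation simulated in one environment)
is combined with the same transformation in a reference environment to give
a relative binding free energy ddG:

* ligand perturbation: ddG = dG(bound) - dG(solvent); positive means the
  transformation is disfavoured in the binding site.
* sidechain mutation:  ddG = dG(complex) - dG(apo); positive means the
  ligand binds the mutant worse than the WT.
* conformational selectivity: ddG(active) - ddG(inactive); positive means
  the perturbation is more unfavourable in the active state, i.e. the
  unperturbed ligand prefers the active conformation.

Non-alanine mutations join two reduction cycles through a common fragment:
ddG(WT->Mut) = ddG(WT->common) - ddG(Mut->common).

Errors propagate in quadrature of the replica s.e.m. values.  ddG converts
to an affinity ratio through ddG = RT ln(KD_mut / KD_wt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import kt
from .errors import ValidationError
from .estimators import LegEstimate

__all__ = ["CycleLeg", "CycleResult", "ligand_ddg", "mutation_ddg",
           "join_dual_cycles", "selectivity_ddg", "ddg_from_kd_ratio",
           "kd_ratio_from_ddg", "cycle_closure"]

ENVIRONMENTS = ("bound", "solvent", "complex", "apo", "active", "inactive")


@dataclass(frozen=True)
class CycleLeg:
    """One directed leg: a transformation estimated in one environment."""

    label: str
    environment: str
    transformation: str  # e.g. "10n->10m", "WT->ALA"
    estimate: LegEstimate

    def __post_init__(self):
        if self.environment not in ENVIRONMENTS:
            raise ValidationError(
                f"environment {self.environment!r} not in {ENVIRONMENTS}")
        if self.estimate is None:
            raise ValidationError("leg estimate missing")


@dataclass(frozen=True)
class CycleResult:
    """A combined ddG with quadrature s.e.m. and its sign convention."""

    ddG: float
    sem: float
    transformation: str
    legs: tuple[CycleLeg, ...] = ()
    interpretation: str = ""

    def __post_init__(self):
        if not math.isfinite(self.ddG):
            raise ValidationError("ddG is not finite")

    def to_dict(self) -> dict:
        return {
            "ddG_kcal_mol": self.ddG,
            "sem_kcal_mol": self.sem,
            "transformation": self.transformation,
            "interpretation": self.interpretation,
            "legs": [
                {"label": l.label, "environment": l.environment,
                 "transformation": l.transformation,
                 "estimate": l.estimate.to_dict()}
                for l in self.legs
            ],
            "units": "kcal/mol",
        }


def _quadrature(*sems: float) -> float:
    return math.sqrt(sum(s * s for s in sems))


def _check_pair(a: CycleLeg, b: CycleLeg, env_a: str, env_b: str) -> None:
    if a.transformation != b.transformation:
        raise ValidationError(
            f"legs describe different transformations: "
            f"{a.transformation!r} vs {b.transformation!r}")
    if a.environment != env_a or b.environment != env_b:
        raise ValidationError(
            f"expected environments ({env_a}, {env_b}), got "
            f"({a.environment}, {b.environment})")


def ligand_ddg(bound: CycleLeg, solvent: CycleLeg) -> CycleResult:
    """Relative binding free energy of a ligand perturbation."""
    _check_pair(bound, solvent, "bound", "solvent")
    return CycleResult(
        ddG=bound.estimate.dG - solvent.estimate.dG,
        sem=_quadrature(bound.estimate.sem, solvent.estimate.sem),
        transformation=bound.transformation,
        legs=(bound, solvent),
        interpretation=("ddG = dG_bound - dG_solvent; positive => "
                        "transformation disfavoured in the binding site"),
    )


def mutation_ddg(complex_leg: CycleLeg, apo: CycleLeg) -> CycleResult:
    """Effect of a sidechain mutation on ligand binding."""
    _check_pair(complex_leg, apo, "complex", "apo")
    return CycleResult(
        ddG=complex_leg.estimate.dG - apo.estimate.dG,
        sem=_quadrature(complex_leg.estimate.sem, apo.estimate.sem),
        transformation=complex_leg.transformation,
        legs=(complex_leg, apo),
        interpretation=("ddG = dG_complex - dG_apo; positive => ligand "
                        "binds the mutant worse than the WT"),
    )


def _split_transformation(t: str) -> tuple[str, str]:
    for arrow in ("->", "→"):
        if arrow in t:
            a, b = t.split(arrow, 1)
            return a.strip(), b.strip()
    raise ValidationError(f"transformation {t!r} lacks an '->' arrow")


def join_dual_cycles(wt_to_common: CycleResult,
                     mut_to_common: CycleResult) -> CycleResult:
    """Join two reduction cycles sharing a common fragment.

    ``ddG(WT->Mut) = ddG(WT->common) - ddG(Mut->common)``; both inputs must
    reduce to the same common fragment (e.g. alanine).
    """
    wt, common1 = _split_transformation(wt_to_common.transformation)
    mut, common2 = _split_transformation(mut_to_common.transformation)
    if common1 != common2:
        raise ValidationError(
            f"cycles reduce to different common fragments: "
            f"{common1!r} vs {common2!r}")
    return CycleResult(
        ddG=wt_to_common.ddG - mut_to_common.ddG,
        sem=_quadrature(wt_to_common.sem, mut_to_common.sem),
        transformation=f"{wt}->{mut}",
        legs=tuple(wt_to_common.legs) + tuple(mut_to_common.legs),
        interpretation=(f"joined via common fragment {common1!r}: "
                        "ddG(WT->Mut) = ddG(WT->common) - ddG(Mut->common)"),
    )


def selectivity_ddg(active: CycleResult, inactive: CycleResult) -> CycleResult:
    """Conformational-selectivity ddG of a ligand perturbation.

    Positive result: the perturbation is more unfavourable in the active
    state, i.e. the unperturbed ligand prefers the active conformation.
    """
    if active.transformation != inactive.transformation:
        raise ValidationError(
            f"results describe different transformations: "
            f"{active.transformation!r} vs {inactive.transformation!r}")
    return CycleResult(
        ddG=active.ddG - inactive.ddG,
        sem=_quadrature(active.sem, inactive.sem),
        transformation=active.transformation,
        legs=tuple(active.legs) + tuple(inactive.legs),
        interpretation=("ddG_selectivity = ddG_active - ddG_inactive; "
                        "positive => perturbation more unfavourable in the "
                        "active state"),
    )


def ddg_from_kd_ratio(ratio: float, temperature: float = 298.15) -> float:
    """ddG = RT ln(KD_mut / KD_wt) in kcal/mol."""
    if ratio <= 0:
        raise ValidationError(f"KD ratio must be positive, got {ratio}")
    return kt(temperature) * math.log(ratio)


def kd_ratio_from_ddg(ddg: float, temperature: float = 298.15) -> float:
    """Inverse of :func:`ddg_from_kd_ratio`: exp(ddG / RT)."""
    return math.exp(ddg / kt(temperature))


def cycle_closure(legs: list[CycleLeg], signs: list[int]) -> float:
    """Signed sum of leg dG values around a closed loop (kcal/mol).

    Each leg is traversed in the direction of its sign (+1 keeps the stated
    transformation direction, -1 reverses it); the traversal must form a
    closed loop over the transformation endpoints.  For consistent data the
    residual vanishes within statistical error.
    """
    if len(legs) < 2:
        raise ValidationError("a loop needs at least 2 legs")
    if len(signs) != len(legs):
        raise ValidationError("need one orientation sign per leg")
    if any(s not in (-1, 1) for s in signs):
        raise ValidationError("orientation signs must be +1 or -1")
    path = []
    for leg, s in zip(legs, signs):
        a, b = _split_transformation(leg.transformation)
        path.append((a, b) if s == 1 else (b, a))
    for (_, end), (start, _) in zip(path, path[1:] + path[:1]):
        if end != start:
            raise ValidationError(
                f"legs do not close a loop: segment ends at {end!r} but the "
                f"next starts at {start!r}")
    return float(sum(s * leg.estimate.dG for leg, s in zip(legs, signs)))
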