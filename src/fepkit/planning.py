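"""Staged alchemical transformation planning.

The FEP protocol annihilates a fragment charge group by charge group,
starting with the group topologically farthest from the anchor atom.  Each
group passes through three stages — removal of its partial charges
(``decharge``), conversion of its van der Waals interactions to a soft-core
form (``softcore``) and annihilation — and one final ``recharge`` stage
restores the partial charges of the end-state species.  Sidechain plans use
21 lambda-windows per stage, ligand plans 51; lambda runs 0 -> 1 in the
direction of annihilation, so "forward" always means initial -> target.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .fragments import FragmentGraph, MutationSpec

__all__ = ["StageStep", "TransformationPlan", "topological_distances",
           "order_charge_groups", "make_lambda_schedule",
           "build_mutation_plan", "build_ligand_plan",
           "read_plan_json", "write_plan_json"]

STAGE_ORDER = ("decharge", "softcore", "annihilate", "recharge")

#: default lambda-windows per stage, by plan kind
DEFAULT_WINDOWS = {"sidechain": 21, "ligand": 51}

#: charge-group label used for the single whole-species recharge stage
END_STATE_GROUP = "end_state"


@dataclass(frozen=True)
class StageStep:
    """One stage applied to one charge group over a lambda schedule."""

    stage: str
    charge_group: str
    lambda_schedule: tuple[float, ...]

    def __post_init__(self):
        if self.stage not in STAGE_ORDER:
            raise ValidationError(f"unknown stage {self.stage!r}")
        lam = tuple(float(x) for x in self.lambda_schedule)
        object.__setattr__(self, "lambda_schedule", lam)
        if len(lam) < 2 or lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValidationError(
                "lambda schedule must span exactly [0, 1] with >= 2 points")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValidationError("lambda schedule must be strictly increasing")


@dataclass(frozen=True)
class TransformationPlan:
    """Ordered staged annihilation/creation schedule over charge groups."""

    steps: tuple[StageStep, ...]
    windows_per_stage: int
    kind: str  # "sidechain" | "ligand"
    label: str = ""

    def __post_init__(self):
        if self.kind not in DEFAULT_WINDOWS:
            raise ValidationError(f"unknown plan kind {self.kind!r}")
        stage_rank = {s: i for i, s in enumerate(STAGE_ORDER)}
        per_group: dict[str, list[int]] = {}
        for step in self.steps:
            per_group.setdefault(step.charge_group, []).append(
                stage_rank[step.stage])
        for group, ranks in per_group.items():
            if ranks != sorted(ranks):
                raise ValidationError(
                    f"stages for group {group!r} violate the "
                    "decharge -> softcore -> annihilate -> recharge order")

    @property
    def removed_groups(self) -> tuple[str, ...]:
        """Charge groups annihilated by this plan, in execution order."""
        seen: list[str] = []
        for s in self.steps:
            if s.stage == "annihilate" and s.charge_group not in seen:
                seen.append(s.charge_group)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "label": self.label,
            "windows_per_stage": self.windows_per_stage,
            "steps": [
                {"stage": s.stage, "charge_group": s.charge_group,
                 "lambda_schedule": list(s.lambda_schedule)}
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformationPlan":
        steps = tuple(
            StageStep(s["stage"], s["charge_group"],
                      tuple(s["lambda_schedule"]))
            for s in d["steps"])
        return cls(steps, int(d["windows_per_stage"]), d["kind"],
                   d.get("label", ""))

    def to_json(self) -> str:
        """Deterministic (byte-stable) JSON serialization."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    def to_table(self) -> str:
        """Human-readable summary table."""
        lines = [f"# {self.kind} plan"
                 + (f" {self.label}" if self.label else "")
                 + f", {self.windows_per_stage} lambda-windows/stage",
                 f"{'step':>4}  {'stage':<10}  {'charge_group':<16}  lambda"]
        for i, s in enumerate(self.steps):
            lam = s.lambda_schedule
            lines.append(f"{i:>4}  {s.stage:<10}  {s.charge_group:<16}  "
                         f"0.00 -> 1.00 ({len(lam)} windows, "
                         f"spacing {lam[1] - lam[0]:.4g})")
        return "\n".join(lines) + "\n"


def topological_distances(graph: FragmentGraph) -> dict[str, int]:
    """Bond-count shortest-path distance of every atom from the anchor.

    Breadth-first search over the bond graph; the anchor maps to 0.  Raises
    :class:`ValidationError` naming unreachable atoms if the graph is
    disconnected.
    """
    return graph.distances_from_anchor(strict=True)


def order_charge_groups(graph: FragmentGraph) -> list[str]:
    """Annihilation order of charge groups.

    Groups are sorted by descending maximum member distance from the anchor,
    ties broken by descending mean member distance and then by ascending
    group label, so the order is deterministic.
    """
    if not graph.atoms:
        raise ValidationError("empty fragment graph")
    dist = topological_distances(graph)
    groups = graph.groups()

    def key(group: str):
        d = [dist[a] for a in groups[group]]
        return (-max(d), -(sum(d) / len(d)), group)

    return sorted(groups, key=key)


def make_lambda_schedule(n: int) -> tuple[float, ...]:
    """``n`` uniformly spaced lambda values from 0 to 1 inclusive."""
    if n < 2:
        raise ValidationError(f"need at least 2 lambda windows, got {n}")
    return tuple(i / (n - 1) for i in range(n))


def _build_plan(spec: MutationSpec, kind: str,
                windows_per_stage: int | None) -> TransformationPlan:
    if windows_per_stage is None:
        windows_per_stage = DEFAULT_WINDOWS[kind]
    if windows_per_stage < 2:
        raise ValidationError("windows_per_stage must be >= 2")
    target_ids = spec.mapped_target_ids()
    wt = spec.wt_fragment
    groups = wt.groups()
    # a group is annihilated iff none of its atoms survive into the target
    removed = [g for g, members in groups.items()
               if not (set(members) & target_ids)]
    order = [g for g in order_charge_groups(wt) if g in removed]
    schedule = make_lambda_schedule(windows_per_stage)
    steps: list[StageStep] = []
    for group in order:
        for stage in ("decharge", "softcore", "annihilate"):
            steps.append(StageStep(stage, group, schedule))
    if steps:
        # single whole-species recharge restores end-state partial charges
        steps.append(StageStep("recharge", END_STATE_GROUP, schedule))
    return TransformationPlan(tuple(steps), windows_per_stage, kind,
                              label=spec.label)


def build_mutation_plan(spec: MutationSpec,
                        windows_per_stage: int | None = None
                        ) -> TransformationPlan:
    """Staged sidechain-mutation plan (default 21 lambda-windows/stage).

    For each WT charge group absent from the target fragment (in annihilation
    order) a decharge, softcore and annihilate step is emitted; a final
    recharge step restores the partial charges of the end-state species.
    An identity mutation yields the empty plan.
    """
    return _build_plan(spec, "sidechain", windows_per_stage)


def build_ligand_plan(spec: MutationSpec,
                      windows_per_stage: int | None = None
                      ) -> TransformationPlan:
    """Staged ligand-fragment perturbation plan (default 51 windows/stage)."""
    return _build_plan(spec, "ligand", windows_per_stage)


def read_plan_json(path: str | Path) -> TransformationPlan:
    with open(path) as fh:
        return TransformationPlan.from_dict(json.load(fh))


def write_plan_json(plan: TransformationPlan, path: str | Path) -> None:
    Path(path).write_text(plan.to_json())
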