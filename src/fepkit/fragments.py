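"""Atom graphs for alchemical fragments.

A :class:`FragmentGraph` is a small molecular graph — a mutated sidechain or a
ligand substituent — carrying per-atom partial charges and force-field-style
charge-group labels.  The graph is anchored at the attachment atom (Calpha for
sidechains, the ring-attachment atom for ligand fragments); topological
distances from the anchor drive the annihilation order of the staged FEP
protocol.

Charge groups are taken from the input labels; the toolkit does not infer
them.  Hydrogens with an empty group label inherit the group of the heavy
atom they are bonded to.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

__all__ = ["AtomNode", "FragmentGraph", "MutationSpec", "read_fragment_json",
           "write_fragment_json"]


@dataclass(frozen=True)
class AtomNode:
    """One atom: unique id, element symbol, partial charge (e), charge group."""

    atom_id: str
    element: str
    partial_charge: float = 0.0
    charge_group: str = ""


@dataclass(frozen=True)
class FragmentGraph:
    """Connected bond graph of a fragment with an anchor (attachment) atom.

    Parameters
    ----------
    atoms:
        The atoms of the fragment.  ``atom_id`` must be unique.
    bonds:
        Unordered pairs of atom ids.
    anchor:
        Atom id of the attachment atom (e.g. ``"CA"``).
    check_group_charge:
        When true (default), each charge group's net partial charge must be
        an integer to within 1e-6 e.
    """

    atoms: tuple[AtomNode, ...]
    bonds: tuple[tuple[str, str], ...]
    anchor: str
    check_group_charge: bool = field(default=True, compare=False)

    def __post_init__(self):
        atoms = tuple(self.atoms)
        bonds = tuple(tuple(sorted(b)) for b in self.bonds)
        object.__setattr__(self, "atoms", _inherit_hydrogen_groups(atoms, bonds))
        object.__setattr__(self, "bonds", bonds)
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate atom ids: {dup}")
        if self.anchor not in ids:
            raise ValidationError(f"anchor {self.anchor!r} not among atoms")
        idset = set(ids)
        for a, b in self.bonds:
            if a not in idset or b not in idset:
                raise ValidationError(f"bond ({a},{b}) references unknown atom")
        for atom in self.atoms:
            if not atom.charge_group:
                raise ValidationError(
                    f"atom {atom.atom_id!r} has an empty charge group")
        # connectivity from the anchor
        unreachable = idset - set(self.distances_from_anchor(strict=False))
        if unreachable:
            raise ValidationError(
                "fragment graph is disconnected; unreachable atoms: "
                + ", ".join(sorted(unreachable)))
        if self.check_group_charge:
            for group, q in sorted(self.group_charges().items()):
                if abs(q - round(q)) > 1e-6:
                    raise ValidationError(
                        f"charge group {group!r} has non-integer net charge "
                        f"{q:.6f} e")

    # -- queries ------------------------------------------------------------

    @property
    def atom_ids(self) -> set[str]:
        return {a.atom_id for a in self.atoms}

    def atom(self, atom_id: str) -> AtomNode:
        for a in self.atoms:
            if a.atom_id == atom_id:
                return a
        raise KeyError(atom_id)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {a.atom_id: [] for a in self.atoms}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def distances_from_anchor(self, strict: bool = True) -> dict[str, int]:
        """Bond-graph shortest-path length of every atom from the anchor (BFS)."""
        adj = {a.atom_id: [] for a in self.atoms}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        dist = {self.anchor: 0}
        queue = deque([self.anchor])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
        if strict and len(dist) != len(self.atoms):
            missing = sorted(self.atom_ids - set(dist))
            raise ValidationError(
                "fragment graph is disconnected; unreachable atoms: "
                + ", ".join(missing))
        return dist

    def group_charges(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for a in self.atoms:
            out[a.charge_group] = out.get(a.charge_group, 0.0) + a.partial_charge
        return out

    def groups(self) -> dict[str, list[str]]:
        """Charge group -> member atom ids."""
        out: dict[str, list[str]] = {}
        for a in self.atoms:
            out.setdefault(a.charge_group, []).append(a.atom_id)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "atoms": [
                {"id": a.atom_id, "element": a.element,
                 "charge": a.partial_charge, "group": a.charge_group}
                for a in self.atoms
            ],
            "bonds": [list(b) for b in self.bonds],
        }

    @classmethod
    def from_dict(cls, d: dict, check_group_charge: bool = True) -> "FragmentGraph":
        try:
            atoms = tuple(
                AtomNode(a["id"], a["element"], float(a.get("charge", 0.0)),
                         a.get("group", ""))
                for a in d["atoms"])
            bonds = tuple((b[0], b[1]) for b in d["bonds"])
            anchor = d["anchor"]
        except (KeyError, TypeError, IndexError) as exc:
            raise ValidationError(f"malformed fragment JSON: {exc}") from exc
        return cls(atoms, bonds, anchor, check_group_charge=check_group_charge)


def _inherit_hydrogen_groups(
    atoms: tuple[AtomNode, ...], bonds: tuple[tuple[str, str], ...]
) -> tuple[AtomNode, ...]:
    """Unlabeled hydrogens take the charge group of their bonded heavy atom."""
    by_id = {a.atom_id: a for a in atoms}
    out = []
    for a in atoms:
        if a.charge_group or a.element != "H":
            out.append(a)
            continue
        heavy_group = ""
        for x, y in bonds:
            other = y if x == a.atom_id else (x if y == a.atom_id else None)
            if other is not None and by_id[other].element != "H":
                heavy_group = by_id[other].charge_group
                break
        out.append(AtomNode(a.atom_id, a.element, a.partial_charge, heavy_group))
    return tuple(out)


@dataclass(frozen=True)
class MutationSpec:
    """A WT -> target fragment transformation (e.g. ``N254A``).

    ``target_fragment`` atoms must be a subset of the WT atoms by id, unless
    an explicit ``mapping`` (target atom id -> WT atom id) is given for a
    common-fragment reduction.
    """

    wt_fragment: FragmentGraph
    target_fragment: FragmentGraph
    label: str = ""
    mapping: tuple[tuple[str, str], ...] | None = None

    def mapped_target_ids(self) -> set[str]:
        """Target atoms expressed as WT atom ids."""
        if self.mapping is not None:
            m = dict(self.mapping)
            unknown = {w for w in m.values()} - self.wt_fragment.atom_ids
            if unknown:
                raise ValidationError(
                    f"mapping references atoms not in WT fragment: {sorted(unknown)}")
            return {m.get(t, t) for t in self.target_fragment.atom_ids}
        missing = self.target_fragment.atom_ids - self.wt_fragment.atom_ids
        if missing:
            raise ValidationError(
                "target fragment is not a subfragment of WT (atoms "
                f"{sorted(missing)} unmatched) and no mapping was supplied")
        return set(self.target_fragment.atom_ids)


def read_fragment_json(path: str | Path, check_group_charge: bool = True) -> FragmentGraph:
    with open(path) as fh:
        return FragmentGraph.from_dict(json.load(fh),
                                       check_group_charge=check_group_charge)


def write_fragment_json(graph: FragmentGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(graph.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
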