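"""Rooted clone trees labelled by acquired mutation sets.

A clone tree describes the nested structure of subclones in a neoplasm under
the infinite-sites assumption: the root is the wild-type clone (empty
mutation set), every child clone carries a strict superset of its parent's
mutations, and each mutation is gained on exactly one edge. Edges may gain
more than one mutation at once — colony data cannot distinguish the order of
mutations that always co-occur.
"""

from __future__ import annotations

import json
from typing import Any, Iterator, Mapping

__all__ = ["CloneTree", "CloneTreeError"]


class CloneTreeError(ValueError):
    """Raised when a clone tree violates the nesting invariants."""


class CloneTree:
    """Rooted tree of clones, each labelled with its full mutation set.

    Parameters
    ----------
    clones
        Mapping from clone identifier to the *full* set of mutation
        identifiers acquired on the path from the root.
    parents
        Mapping from clone identifier to parent identifier; the root maps
        to ``None``.
    root
        Identifier of the wild-type root clone.
    meta
        Optional per-clone annotations (e.g. colony counts); not part of
        the structural invariants.
    """

    def __init__(
        self,
        clones: Mapping[str, frozenset[str]],
        parents: Mapping[str, str | None],
        root: str = "WT",
        meta: Mapping[str, Any] | None = None,
    ) -> None:
        self.clones: dict[str, frozenset[str]] = {c: frozenset(m) for c, m in clones.items()}
        self.parents: dict[str, str | None] = dict(parents)
        self.root = root
        self.meta: dict[str, Any] = dict(meta or {})
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.root not in self.clones:
            raise CloneTreeError(f"root {self.root!r} not among clones")
        if self.clones[self.root]:
            raise CloneTreeError("root clone must carry the empty mutation set")
        if self.parents.get(self.root) is not None:
            raise CloneTreeError("root must have no parent")
        if set(self.parents) != set(self.clones):
            raise CloneTreeError("parents and clones must cover the same identifiers")
        gained: dict[str, str] = {}
        for child, parent in self.parents.items():
            if child == self.root:
                continue
            if parent not in self.clones:
                raise CloneTreeError(f"parent {parent!r} of {child!r} unknown")
            pset, cset = self.clones[parent], self.clones[child]
            if not (pset < cset):
                raise CloneTreeError(
                    f"clone {child!r} must carry a strict superset of its parent's mutations"
                )
            for m in cset - pset:
                if m in gained:
                    raise CloneTreeError(f"mutation {m!r} gained on more than one edge")
                gained[m] = child
        # reachability / acyclicity
        for clone in self.clones:
            seen = set()
            cur: str | None = clone
            while cur is not None:
                if cur in seen:
                    raise CloneTreeError("cycle in parent relation")
                seen.add(cur)
                cur = self.parents[cur]
            if self.root not in seen:
                raise CloneTreeError(f"clone {clone!r} not connected to root")

    # -- queries -----------------------------------------------------------
    @property
    def mutations(self) -> frozenset[str]:
        out: set[str] = set()
        for mset in self.clones.values():
            out |= mset
        return frozenset(out)

    def children(self, clone: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == clone)

    def edge_mutations(self, child: str) -> frozenset[str]:
        """Mutations newly acquired on the edge into *child*."""
        parent = self.parents[child]
        if parent is None:
            return frozenset()
        return self.clones[child] - self.clones[parent]

    def leaves(self) -> list[str]:
        have_children = set(p for p in self.parents.values() if p is not None)
        return sorted(c for c in self.clones if c not in have_children)

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.clones))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        # structural equality: same signature sets and same parent relation
        # between signatures, independent of clone identifiers
        sig = {self.clones[c]: (self.clones[p] if (p := self.parents[c]) is not None else None)
               for c in self.clones}
        osig = {other.clones[c]: (other.clones[p] if (p := other.parents[c]) is not None else None)
                for c in other.clones}
        return sig == osig

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "root": self.root,
            "clones": {c: sorted(m) for c, m in self.clones.items()},
            "parents": self.parents,
            "edge_mutations": {
                c: sorted(self.edge_mutations(c)) for c in self.clones if c != self.root
            },
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CloneTree":
        return cls(
            {c: frozenset(m) for c, m in data["clones"].items()},
            dict(data["parents"]),
            root=data["root"],
            meta=data.get("meta"),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CloneTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def render_text(self) -> str:
        """Indented-text rendering, one clone per line."""
        lines: list[str] = []

        def walk(clone: str, depth: int) -> None:
            gained = sorted(self.edge_mutations(clone))
            label = "+".join(gained) if gained else "wild type"
            lines.append("  " * depth + f"{clone} [{label}]")
            for child in self.children(clone):
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CloneTree(n_clones={len(self)}, n_mutations={len(self.mutations)})"
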