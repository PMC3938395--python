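"""Pedigree topology, kinship coefficients and truth labels.

A pedigree is a list of members, each with both parents present or
both absent (founders).  Pairwise kinship coefficients are computed
with the standard recursive algorithm over a topological ordering, and
the degree of relationship is derived from the kinship coefficient
``phi`` as ``round(-log2(2*phi))`` — parent-offspring and full
siblings are both 1st degree, and each further degree halves the
expected sharing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class Member:
    id: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None


class PedigreeError(ValueError):
    pass


class Pedigree:
    def __init__(self, members: list[Member]):
        self.members: dict[str, Member] = {}
        for m in members:
            if m.id in self.members:
                raise PedigreeError(f"duplicate member id {m.id!r}")
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(
                    f"member {m.id!r} must have both parents or neither"
                )
            self.members[m.id] = m
        for m in members:
            for p in (m.father, m.mother):
                if p is not None and p not in self.members:
                    raise PedigreeError(f"member {m.id!r} references unknown parent {p!r}")
        self._order = self._topological_order()
        self._kinship: dict[frozenset, float] | None = None

    # -- structure ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.members)

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members.values() if m.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [m.id for m in self.members.values() if not m.is_founder]

    def _topological_order(self) -> list[str]:
        """Parents before children; raises on cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 in progress, 2 done

        def visit(mid: str) -> None:
            if state.get(mid) == 2:
                return
            if state.get(mid) == 1:
                raise PedigreeError(f"pedigree cycle involving {mid!r}")
            state[mid] = 1
            m = self.members[mid]
            if m.father is not None:
                visit(m.father)
                visit(m.mother)
            state[mid] = 2
            order.append(mid)

        for mid in self.members:
            visit(mid)
        return order

    @property
    def topological_order(self) -> list[str]:
        return list(self._order)

    # -- kinship -----------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b)."""
        if self._kinship is None:
            self._kinship = self._compute_kinship()
        return self._kinship[frozenset((a, b))]

    def _compute_kinship(self) -> dict[frozenset, float]:
        rank = {mid: i for i, mid in enumerate(self._order)}
        phi: dict[frozenset, float] = {}

        def get(a: str, b: str) -> float:
            key = frozenset((a, b))
            if key in phi:
                return phi[key]
            if a == b:
                m = self.members[a]
                val = 0.5 * (
                    1 + (get(m.father, m.mother) if m.father is not None else 0.0)
                )
            else:
                # recurse through the parents of the later-ranked member:
                # its parents cannot be descendants of the other member
                if rank[a] < rank[b]:
                    a, b = b, a
                m = self.members[a]
                if m.father is None:
                    val = 0.0
                else:
                    val = 0.5 * (get(m.father, b) + get(m.mother, b))
            phi[key] = val
            return val

        ids = list(self.members)
        for i, x in enumerate(ids):
            for y in ids[i:]:
                get(x, y)
        return phi

    def degree(self, a: str, b: str) -> int | None:
        """Degree of relationship, or None for unrelated; 0 for self."""
        phi = self.kinship(a, b)
        if phi == 0:
            return None
        return round(-math.log2(2 * phi))

    def relationship_label(self, a: str, b: str) -> str:
        """Truth label: IT, PO, FS, D2..Dn, or UN."""
        if a == b:
            return "IT"
        d = self.degree(a, b)
        if d is None:
            return "UN"
        if d == 0:
            return "IT"
        if d == 1:
            ma, mb = self.members[a], self.members[b]
            if b in (ma.father, ma.mother) or a in (mb.father, mb.mother):
                return "PO"
            return "FS"
        return f"D{d}"

    def pair_labels(self, include_self: bool = False) -> list[tuple[str, str, str]]:
        """All (a, b, label) with a < b lexicographically (plus self pairs)."""
        ids = sorted(self.members)
        out = []
        if include_self:
            out.extend((i, i, "IT") for i in ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                out.append((a, b, self.relationship_label(a, b)))
        return out

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_ped_file(cls, path) -> "Pedigree":
        """Read a 5/6-column whitespace table: [family] id father mother sex.

        '0' denotes a missing parent, following the PED convention.
        A leading family column is detected by column count.
        """
        members = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) >= 5:
                _fam, mid, fa, mo, sex = fields[:5]
            elif len(fields) == 4:
                mid, fa, mo, sex = fields
            else:
                raise PedigreeError(f"{path}:{lineno}: expected >=4 columns")
            members.append(
                Member(
                    id=mid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=int(sex) if sex.isdigit() else 0,
                )
            )
        if not members:
            raise PedigreeError(f"{path}: no pedigree members")
        return cls(members)

    def to_ped_file(self, path, family_id: str = "FAM1") -> None:
        lines = [
            f"{family_id} {m.id} {m.father or 0} {m.mother or 0} {m.sex}"
            for m in self.members.values()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def default_family_pedigree() -> Pedigree:
    """The packaged 26-member, 7-generation training family.

    Ten founders (A1, A2 and the marry-in spouses X1..X8) and sixteen
    simulated descendants arranged so that the family contains
    full-sibling, parent-offspring and 2nd- through 7th-degree pairs,
    while founder-founder pairs provide unrelated examples.
    """
    m = Member
    return Pedigree(
        [
            # generation 1
            m("A1", None, None, 1),
            m("A2", None, None, 2),
            # generation 2: sibs B1, B2 and their spouses
            m("B1", "A1", "A2", 1),
            m("B2", "A1", "A2", 2),
            m("X1", None, None, 2),
            m("X2", None, None, 1),
            # generation 3
            m("C1", "B1", "X1", 1),
            m("C2", "B1", "X1", 2),
            m("C3", "X2", "B2", 2),
            m("X3", None, None, 2),
            m("X4", None, None, 1),
            # generation 4
            m("D1", "C1", "X3", 1),
            m("D2", "C1", "X3", 2),
            m("D3", "X4", "C3", 1),
            m("D4", "X4", "C3", 2),
            m("X5", None, None, 2),
            m("X6", None, None, 2),
            # generation 5
            m("E1", "D1", "X5", 1),
            m("E2", "D1", "X5", 2),
            m("E3", "D3", "X6", 1),
            m("X7", None, None, 2),
            # generation 6
            m("F1", "E1", "X7", 1),
            m("F2", "E1", "X7", 2),
            m("X8", None, None, 2),
            # generation 7
            m("G1", "F1", "X8", 1),
            m("G2", "F1", "X8", 2),
        ]
    )
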