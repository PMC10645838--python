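"""Fructan polymers as rooted trees of hexose residues.

A fructan is modelled as a connected acyclic graph of glucose/fructose
residues. Every glycosidic bond is an edge ``(donor, acceptor, position)``
where the donor engages its anomeric carbon (fructose C2, glucose C1) and
the acceptor is substituted at the named carbon. The sucrose moiety is the
unique edge donated by the (at most one) glucose; its acceptor position is
the fructose anomeric C2, which never counts as a substitution.

The substitution pattern of a residue determines its PMAA linkage class,
so the linkage census of a structure is a pure function of the tree — the
pivot between forward simulation and the inference procedure.

A counting identity constrains which censuses are realizable as trees.
Summing child edges over residue classes (2-1/2-6 residues hold one child,
di residues two, internal glucose two, terminal glucose one) and equating
with ``n_residues - 1`` forces::

    #t-Fruf == #di-Fruf + 1 + (1 if glucose internal else 0)

``assemble_core`` enforces exactly this identity; censuses violating it do
not correspond to any tree.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .linkages import LinkageClass

GLUCOSE = "glucose"
FRUCTOSE = "fructose"

#: acceptor position of the sucrose bond (fructose anomeric carbon)
ANOMERIC = "C2"

SCHEMA_VERSION = "fructan-1"


class StructureError(ValueError):
    """A malformed residue tree (cycle, bad position, two glucoses...)."""


class InfeasibleCensusError(StructureError):
    """A linkage census that no residue tree can realize."""


@dataclass(frozen=True)
class Residue:
    id: str
    sugar: str  # "glucose" | "fructose"


class FructanStructure:
    """Rooted residue tree with typed glycosidic linkages.

    Parameters
    ----------
    residues
        Iterable of :class:`Residue` (or ``(id, sugar)`` pairs).
    edges
        Iterable of ``(donor_id, acceptor_id, position)`` triples, position
        in {"C1", "C2", "C6"}; "C2" is legal only for the glucose-donated
        sucrose bond.
    """

    def __init__(
        self,
        residues: Iterable[Residue | tuple[str, str]],
        edges: Iterable[tuple[str, str, str]],
        validate: bool = True,
    ) -> None:
        self.residues: dict[str, Residue] = {}
        for r in residues:
            if not isinstance(r, Residue):
                r = Residue(*r)
            if r.id in self.residues:
                raise StructureError(f"duplicate residue id {r.id!r}")
            self.residues[r.id] = r
        self.edges: list[tuple[str, str, str]] = [tuple(e) for e in edges]
        if validate:
            self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.residues:
            raise StructureError("empty structure")
        glucoses = [r for r in self.residues.values() if r.sugar == GLUCOSE]
        for r in self.residues.values():
            if r.sugar not in (GLUCOSE, FRUCTOSE):
                raise StructureError(f"residue {r.id!r}: unknown sugar {r.sugar!r}")
        if len(glucoses) > 1:
            ids = ", ".join(r.id for r in glucoses)
            raise StructureError(
                f"at most one glucose allowed per fructan; found {ids}"
            )

        g = nx.Graph()
        g.add_nodes_from(self.residues)
        donors: set[str] = set()
        acceptor_slots: set[tuple[str, str]] = set()
        for donor, acceptor, pos in self.edges:
            for rid in (donor, acceptor):
                if rid not in self.residues:
                    raise StructureError(f"edge references unknown residue {rid!r}")
            dsug = self.residues[donor].sugar
            asug = self.residues[acceptor].sugar
            if dsug == GLUCOSE:
                if asug != FRUCTOSE or pos != ANOMERIC:
                    raise StructureError(
                        f"glucose {donor!r} may only donate the sucrose bond "
                        f"(fructose acceptor at {ANOMERIC}); got {acceptor!r}@{pos}"
                    )
            else:
                allowed = ("C1", "C6") if asug == FRUCTOSE else ("C6",)
                if pos not in allowed:
                    raise StructureError(
                        f"residue {acceptor!r} ({asug}) cannot accept at {pos}"
                    )
            if donor in donors:
                raise StructureError(
                    f"residue {donor!r} donates twice (anomeric carbon reused)"
                )
            donors.add(donor)
            slot = (acceptor, pos)
            if slot in acceptor_slots:
                raise StructureError(
                    f"residue {acceptor!r} substituted twice at {pos}"
                )
            acceptor_slots.add(slot)
            g.add_edge(donor, acceptor)

        n = len(self.residues)
        if len(self.edges) != n - 1 or (n > 1 and not nx.is_connected(g)):
            raise StructureError(
                "residue graph is not a tree "
                f"(|edges|={len(self.edges)}, |residues|={n})"
            )
        if glucoses and n > 1 and glucoses[0].id not in donors:
            raise StructureError(
                f"glucose {glucoses[0].id!r} lacks its sucrose bond"
            )

    # -- basic accessors -----------------------------------------------
    @property
    def glucose_id(self) -> str | None:
        for r in self.residues.values():
            if r.sugar == GLUCOSE:
                return r.id
        return None

    @property
    def root(self) -> str:
        """The glucose if present, else the unique non-donating fructose."""
        gid = self.glucose_id
        if gid is not None:
            return gid
        donors = {d for d, _, _ in self.edges}
        for rid in self.residues:
            if rid not in donors:
                return rid
        raise StructureError("no root residue found")  # pragma: no cover

    def substituted_positions(self, rid: str) -> frozenset[str]:
        """Non-anomeric positions of ``rid`` occupied by incoming donors."""
        return frozenset(
            pos for _, acc, pos in self.edges if acc == rid and pos != ANOMERIC
        )

    def dp(self) -> int:
        """Degree of polymerization: number of hexose units."""
        return len(self.residues)

    # -- census ----------------------------------------------------------
    def residue_class(self, rid: str) -> LinkageClass:
        r = self.residues[rid]
        subs = self.substituted_positions(rid)
        if r.sugar == GLUCOSE:
            if not subs:
                return LinkageClass.T_GLCP
            if subs == {"C6"}:
                return LinkageClass.I_GLCP
            raise StructureError(f"glucose {rid!r} substituted at {sorted(subs)}")
        if not subs:
            return LinkageClass.T_FRUF
        if subs == {"C1"}:
            return LinkageClass.B21_FRUF
        if subs == {"C6"}:
            return LinkageClass.B26_FRUF
        if subs == {"C1", "C6"}:
            return LinkageClass.DI_FRUF
        raise StructureError(f"fructose {rid!r} substituted at {sorted(subs)}")

    def census(self) -> dict[LinkageClass, int]:
        """Count residues per PMAA linkage class; values sum to the DP."""
        counts = {c: 0 for c in LinkageClass}
        for rid in self.residues:
            counts[self.residue_class(rid)] += 1
        return counts

    # -- topology --------------------------------------------------------
    def classify_topology(self) -> str:
        """Label the fructan class of this structure.

        F-series (no glucose); inulin/levan (terminal glucose, linear, by
        dominant linkage); inulin-neo-series (internal glucose, linear);
        graminan (terminal glucose, branched); agavin (internal glucose,
        branched). A branch is a 1,6-di-substituted fructose.
        """
        c = self.census()
        has_glc = c[LinkageClass.T_GLCP] + c[LinkageClass.I_GLCP] > 0
        if not has_glc:
            return "F-series"
        internal = c[LinkageClass.I_GLCP] > 0
        branched = c[LinkageClass.DI_FRUF] > 0
        if internal:
            return "agavin" if branched else "inulin-neo-series"
        if branched:
            return "graminan"
        return "levan" if c[LinkageClass.B26_FRUF] > c[LinkageClass.B21_FRUF] else "inulin"

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "root": self.root,
            "residues": [
                {"id": r.id, "sugar": r.sugar} for r in self.residues.values()
            ],
            "edges": [
                {"donor": d, "acceptor": a, "position": p} for d, a, p in self.edges
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FructanStructure":
        if d.get("schema") != SCHEMA_VERSION:
            raise StructureError(f"unsupported schema {d.get('schema')!r}")
        return cls(
            [(r["id"], r["sugar"]) for r in d["residues"]],
            [(e["donor"], e["acceptor"], e["position"]) for e in d["edges"]],
        )

    @classmethod
    def from_json(cls, s: str) -> "FructanStructure":
        return cls.from_dict(json.loads(s))

    def condensed(self) -> str:
        """Human-readable one-line rendering, for logs only."""
        children: dict[str, list[tuple[str, str]]] = {rid: [] for rid in self.residues}
        incoming: dict[str, list[tuple[str, str]]] = {rid: [] for rid in self.residues}
        for d, a, p in self.edges:
            incoming[a].append((p, d))

        # orient the tree away from the root regardless of donor direction
        seen: set[str] = set()

        def render(rid: str) -> str:
            seen.add(rid)
            r = self.residues[rid]
            label = "G" if r.sugar == GLUCOSE else "F"
            parts = []
            for d, a, p in self.edges:
                if d == rid and a not in seen:
                    parts.append((p, a))
                elif a == rid and d not in seen:
                    parts.append((p + "<", d))
            inner = "".join(
                f"[{p}:{render(o)}]" for p, o in sorted(parts, key=lambda x: x[0])
            )
            return label + inner

        return render(self.root)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FructanStructure DP={self.dp()} {self.classify_topology()}>"


# ---------------------------------------------------------------------------
# census helpers and canonical assembly
# ---------------------------------------------------------------------------

def census(structure: FructanStructure) -> dict[LinkageClass, int]:
    return structure.census()


def dp(structure: FructanStructure) -> int:
    return structure.dp()


def classify_topology(structure: FructanStructure) -> str:
    return structure.classify_topology()


def _as_counts(counts: Mapping) -> dict[LinkageClass, int]:
    out = {c: 0 for c in LinkageClass}
    for k, v in counts.items():
        key = LinkageClass(k) if not isinstance(k, LinkageClass) else k
        iv = int(round(float(v)))
        if abs(iv - float(v)) > 1e-9 or iv < 0:
            raise InfeasibleCensusError(
                f"census counts must be non-negative integers; {key}: {v}"
            )
        out[key] = iv
    return out


def required_terminals(n_di: int, internal_glucose: bool) -> int:
    """Terminal fructoses any tree with ``n_di`` branch residues must have."""
    return n_di + 1 + (1 if internal_glucose else 0)


def _split_even(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def assemble_core(
    counts: Mapping, glucose_mode: str = "terminal"
) -> FructanStructure:
    """Build the canonical structure realizing a linkage census.

    Canonical layout: glucose at the root; one backbone chain from the
    sucrose fructose holding all 2-1 residues with the di residues spaced
    evenly along it (glucose-proximal first); each di carries a levan chain
    at C6 (the 2-6 residues split evenly across branches); when there is no
    branch residue the 2-6 run sits at the distal end of the backbone; every
    open chain ends in a terminal fructose; in ``internal`` mode one
    terminal fructose occupies glucose C6 (the neo position).

    Raises :class:`InfeasibleCensusError` when the census violates the tree
    identity ``t-Fruf == di-Fruf + 1 + internal``.
    """
    if glucose_mode not in ("terminal", "internal"):
        raise ValueError(f"glucose_mode must be terminal|internal, got {glucose_mode!r}")
    c = _as_counts(counts)
    n_glc = c[LinkageClass.T_GLCP] + c[LinkageClass.I_GLCP]
    if n_glc > 1:
        raise InfeasibleCensusError("census has more than one glucose")
    internal = glucose_mode == "internal"
    n_t, n1, n6, nd = (
        c[LinkageClass.T_FRUF],
        c[LinkageClass.B21_FRUF],
        c[LinkageClass.B26_FRUF],
        c[LinkageClass.DI_FRUF],
    )
    need_t = required_terminals(nd, internal)
    if n_t != need_t:
        raise InfeasibleCensusError(
            f"no tree realizes this census: terminal fructoses must equal "
            f"di + 1 + internal = {need_t}, got {n_t}"
        )

    residues: list[tuple[str, str]] = [("G", GLUCOSE)]
    edges: list[tuple[str, str, str]] = []
    counter = iter(range(1, n_t + n1 + n6 + nd + 2))

    def new_f() -> str:
        rid = f"F{next(counter)}"
        residues.append((rid, FRUCTOSE))
        return rid

    # The backbone starts at the sucrose fructose. A residue's class is set
    # by the position its child occupies on it, so building a chain means
    # walking a list of positions; the last residue (no child) is a terminal.
    suc = new_f()
    edges.append(("G", suc, ANOMERIC))
    if nd > 0:
        seg = _split_even(n1, nd)
        levan = _split_even(n6, nd)
        cur = suc
        for i in range(nd):
            # di residue; the sucrose fructose itself heads the first branch
            di = cur if i == 0 else new_f()
            if di is not cur:
                edges.append((di, cur, "C1"))
            # levan branch at C6: a run of 2-6 residues then a terminal cap
            lev = di
            for _ in range(levan[i] + 1):  # +1 for the cap
                nxt = new_f()
                edges.append((nxt, lev, "C6"))
                lev = nxt
            # 2-1 segment continuing the backbone at C1
            cur = di
            for _ in range(seg[i]):
                nxt = new_f()
                edges.append((nxt, cur, "C1"))
                cur = nxt
        cap = new_f()
        edges.append((cap, cur, "C1"))
    else:
        # single chain: 2-1 run, then 2-6 run; the last residue is the cap
        cur = suc
        for pos in ["C1"] * n1 + ["C6"] * n6:
            nxt = new_f()
            edges.append((nxt, cur, pos))
            cur = nxt

    if internal:
        neo = new_f()
        edges.append((neo, "G", "C6"))

    structure = FructanStructure(residues, edges)
    got = structure.census()
    expect = dict(c)
    expect[LinkageClass.T_GLCP] = 0 if internal else 1
    expect[LinkageClass.I_GLCP] = 1 if internal else 0
    assert got == expect, f"assembly census mismatch: {got} != {expect}"
    return structure


def _backbone_head(structure: FructanStructure) -> str:
    """Glucose-proximal end of the inulin backbone (the sucrose fructose),
    or the root itself for F-series chains."""
    gid = structure.glucose_id
    if gid is None:
        return structure.root
    return next(a for d, a, p in structure.edges if d == gid and p == ANOMERIC)


def extend_to_target_dp(
    core: FructanStructure, target_dp: int, mode: str = "backbone"
) -> FructanStructure:
    """Grow a core structure to a larger degree of polymerization.

    ``backbone`` inserts 2->1 fructoses at the distal end of the inulin
    backbone until the DP matches (exact). ``proportional`` multiplies every
    non-glucose class count by ``target_dp / dp(core)``, applies the
    molecule-assignment rounding, canonicalises the terminal count to the
    tree identity (exchanging surplus/deficit terminals with 2-1 units, DP
    conserved) and reassembles; the resulting DP tracks the scaled census,
    not ``target_dp`` exactly.
    """
    if target_dp < core.dp():
        raise StructureError(
            f"target DP {target_dp} below core DP {core.dp()}"
        )
    if target_dp == core.dp():
        return FructanStructure(
            list(core.residues.values()), list(core.edges)
        )
    if mode == "backbone":
        # splice the new 2->1 run just below the backbone head so existing
        # residues keep their substitution patterns (hence their classes)
        residues = list(core.residues.values())
        edges = list(core.edges)
        head = _backbone_head(core)
        old = next((e for e in edges if e[1] == head and e[2] == "C1"), None)
        if old is not None:
            edges.remove(old)
        cur = head
        last = None
        for i in range(target_dp - core.dp()):
            rid = f"X{i + 1}"
            residues.append(Residue(rid, FRUCTOSE))
            edges.append((rid, cur, "C1"))
            cur = rid
            last = rid
        if old is not None:
            edges.append((old[0], last, "C1"))
        return FructanStructure(residues, edges)
    if mode == "proportional":
        from .inference import assign_value  # late import, no cycle at module load

        factor = target_dp / core.dp()
        c = core.census()
        internal = c[LinkageClass.I_GLCP] > 0
        if c[LinkageClass.T_GLCP] + c[LinkageClass.I_GLCP] == 0:
            raise StructureError("proportional extension needs a glucose root")
        scaled = {
            cls: assign_value(c[cls] * factor)
            for cls in (
                LinkageClass.T_FRUF,
                LinkageClass.B21_FRUF,
                LinkageClass.B26_FRUF,
                LinkageClass.DI_FRUF,
            )
        }
        need_t = required_terminals(scaled[LinkageClass.DI_FRUF], internal)
        surplus = scaled[LinkageClass.T_FRUF] - need_t
        scaled[LinkageClass.T_FRUF] = need_t
        scaled[LinkageClass.B21_FRUF] += surplus
        if scaled[LinkageClass.B21_FRUF] < 0:
            raise InfeasibleCensusError(
                "scaled census cannot be canonicalised: not enough 2-1 units "
                "to supply the required terminal fructoses"
            )
        scaled[LinkageClass.I_GLCP] = 1 if internal else 0
        scaled[LinkageClass.T_GLCP] = 0 if internal else 1
        return assemble_core(scaled, "internal" if internal else "terminal")
    raise ValueError(f"unknown extension mode {mode!r}")
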