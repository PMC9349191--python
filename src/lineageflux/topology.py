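"""Lineage pathway graphs and enumeration of candidate topologies.

A lineage topology is a directed graph of hematopoietic compartments
(stem cells, progenitors, committed cells) connected by differentiation
edges.  Compartments sit on a grid: a *level* (stage index, 0 at the tip
stem cells and increasing downstream) and a *column* (a categorical
marker state such as the Sca-1 surface level).  Differentiation edges
are *vertical* (next stage, same marker state), *horizontal* (same
stage, marker change) or *diagonal* (both).  Differentiation is
unidirectional: an edge never decreases the stage index, so the only
"reverse" moves are horizontal marker reversions (e.g. Sca-1 lo -> hi).

Candidate models of hematopoiesis differ only in which edges of a fixed
superposed *possibility graph* they retain; enumerating the admissible
edge subsets produces the model space that is then ranked against data
by AICc.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import networkx as nx

__all__ = [
    "Compartment",
    "DifferentiationEdge",
    "LineageTopology",
    "EnumerationRules",
    "TopologyFeatures",
    "TopologyError",
    "build_possibility_graph",
    "preset_rules",
    "enumerate_subtopologies",
    "classify_topology",
    "PRESET_NAMES",
]

PRESET_NAMES = ("hsc_to_cmp_clp", "thrombopoiesis_full", "toy", "hsc_best")


class TopologyError(ValueError):
    """A topology or rule set violates a structural invariant."""


@dataclass(frozen=True)
class Compartment:
    """One cell population of the model.

    Parameters
    ----------
    id : str
        Short unique key (e.g. ``"HSC_lo"``).
    label : str
        Display name (e.g. ``"CD201-/lo Sca-1lo HSC"``).
    level : int
        Stage index; 0 for the tip stem cells, increasing downstream.
    column : str
        Marker-state column (e.g. ``"Sca1_hi"``).
    observed : bool
        Whether measurements exist for this compartment.
    is_tip : bool
        Tip (label-source) compartment; exactly one per topology.
    allows_proliferation, allows_loss : bool
        Whether the kinetic model may assign a nonzero proliferation or
        loss rate to this compartment.
    """

    id: str
    label: str = ""
    level: int = 0
    column: str = ""
    observed: bool = True
    is_tip: bool = False
    allows_proliferation: bool = True
    allows_loss: bool = False


@dataclass(frozen=True)
class DifferentiationEdge:
    source: str
    target: str
    kind: str = ""  # vertical | horizontal | diagonal; derived if empty

    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class TopologyFeatures:
    """Feature classification of a candidate topology.

    ``parallel_pathways``: every marker column carries a complete
    differentiation chain (vertical edges link all consecutive stages
    present in the column, and the column is entered from upstream).
    ``irreversible_column_loss``: the topology contains no horizontal
    edge that reverts the marker state (column rank decreases).
    """

    parallel_pathways: bool
    irreversible_column_loss: bool

    @property
    def class_label(self) -> str:
        if self.parallel_pathways and self.irreversible_column_loss:
            return "parallel+irreversible"
        if self.parallel_pathways:
            return "parallel only"
        if self.irreversible_column_loss:
            return "irreversible only"
        return "neither"


@dataclass(frozen=True)
class EnumerationRules:
    """Constraints defining the admissible model space of a preset."""

    required_terminals: tuple[str, ...]
    allow_reverse_column_change: bool = True
    require_all_compartments_reachable: bool = True
    mandatory_edges: tuple[tuple[str, str], ...] = ()
    forbidden_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not self.required_terminals:
            raise TopologyError("required_terminals must be non-empty")
        object.__setattr__(self, "required_terminals", tuple(self.required_terminals))
        object.__setattr__(
            self, "mandatory_edges", tuple(tuple(e) for e in self.mandatory_edges)
        )
        object.__setattr__(
            self, "forbidden_edges", tuple(tuple(e) for e in self.forbidden_edges)
        )


class LineageTopology:
    """A directed graph of compartments with differentiation edges."""

    def __init__(
        self,
        compartments: list[Compartment],
        edges: list[DifferentiationEdge],
        name: str = "",
        column_order: tuple[str, ...] | None = None,
        validate: bool = True,
        require_reachable: bool = True,
    ):
        self.compartments = list(compartments)
        self._by_id = {c.id: c for c in self.compartments}
        self.edges = [self._with_kind(e) for e in edges]
        if column_order is None:
            seen: dict[str, None] = {}
            for c in sorted(self.compartments, key=lambda c: (c.level,)):
                seen.setdefault(c.column, None)
            column_order = tuple(seen)
        self.column_order = tuple(column_order)
        self.name = name or self.edge_hash()
        if validate:
            self.validate(require_reachable=require_reachable)

    # -- construction helpers -------------------------------------------------

    def _with_kind(self, e: DifferentiationEdge) -> DifferentiationEdge:
        try:
            src, dst = self._by_id[e.source], self._by_id[e.target]
        except KeyError as err:
            raise TopologyError(f"edge references unknown compartment: {err}") from None
        kind = classify_edge_kind(src, dst)
        if e.kind and e.kind != kind:
            raise TopologyError(
                f"edge {e.source}->{e.target} declared {e.kind!r} but geometry says {kind!r}"
            )
        return replace(e, kind=kind)

    def edge_hash(self) -> str:
        payload = ";".join(f"{s}>{t}" for s, t in self.edge_keys())
        return "t" + hashlib.sha1(payload.encode()).hexdigest()[:10]

    # -- basic queries --------------------------------------------------------

    def compartment(self, cid: str) -> Compartment:
        return self._by_id[cid]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compartments]

    @property
    def tip(self) -> Compartment:
        tips = [c for c in self.compartments if c.is_tip]
        if len(tips) != 1:
            raise TopologyError(f"expected exactly one tip, found {len(tips)}")
        return tips[0]

    def edge_keys(self) -> list[tuple[str, str]]:
        return sorted(e.key() for e in self.edges)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(self.edge_keys())
        return g

    def in_edges(self, cid: str) -> list[DifferentiationEdge]:
        return [e for e in self.edges if e.target == cid]

    def out_edges(self, cid: str) -> list[DifferentiationEdge]:
        return [e for e in self.edges if e.source == cid]

    def column_rank(self, column: str) -> int:
        try:
            return self.column_order.index(column)
        except ValueError:
            return len(self.column_order)

    # -- invariants -----------------------------------------------------------

    def validate(self, require_reachable: bool = True) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise TopologyError("compartment ids are not unique")
        tip = self.tip
        if tip.level != 0:
            raise TopologyError(f"tip {tip.id!r} must have level 0")
        seen_edges = set()
        for e in self.edges:
            if e.source == e.target:
                raise TopologyError(f"self-edge on {e.source!r}")
            if e.key() in seen_edges:
                raise TopologyError(f"duplicate edge {e.source}->{e.target}")
            seen_edges.add(e.key())
            src, dst = self._by_id[e.source], self._by_id[e.target]
            if e.kind in ("vertical", "diagonal") and dst.level <= src.level:
                raise TopologyError(
                    f"edge {e.source}->{e.target} does not increase level "
                    f"({src.level} -> {dst.level}): differentiation is unidirectional"
                )
            if dst.id == tip.id:
                raise TopologyError(f"tip {tip.id!r} has incoming edge from {e.source!r}")
        if require_reachable:
            unreachable = self.unreachable_compartments()
            if unreachable:
                raise TopologyError(
                    f"compartments not reachable from tip: {sorted(unreachable)}"
                )

    def unreachable_compartments(self) -> set[str]:
        reach = nx.descendants(self.graph(), self.tip.id) | {self.tip.id}
        return set(self.ids) - reach

    # -- derived topologies ---------------------------------------------------

    def with_edges(
        self, edge_keys, name: str = "", require_reachable: bool = True
    ) -> "LineageTopology":
        """New topology on the same compartment roster with the given edge set."""
        edges = [DifferentiationEdge(s, t) for s, t in sorted(edge_keys)]
        return LineageTopology(
            self.compartments,
            edges,
            name=name,
            column_order=self.column_order,
            require_reachable=require_reachable,
        )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "column_order": list(self.column_order),
            "compartments": [
                {
                    "id": c.id,
                    "label": c.label,
                    "level": c.level,
                    "column": c.column,
                    "observed": c.observed,
                    "is_tip": c.is_tip,
                    "allows_proliferation": c.allows_proliferation,
                    "allows_loss": c.allows_loss,
                }
                for c in self.compartments
            ],
            "edges": [
                {"source": e.source, "target": e.target, "kind": e.kind}
                for e in sorted(self.edges, key=lambda e: e.key())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, require_reachable: bool = True) -> "LineageTopology":
        comps = [Compartment(**c) for c in d["compartments"]]
        edges = [DifferentiationEdge(**e) for e in d["edges"]]
        return cls(
            comps,
            edges,
            name=d.get("name", ""),
            column_order=tuple(d["column_order"]) if "column_order" in d else None,
            require_reachable=require_reachable,
        )

    def __eq__(self, other):
        return (
            isinstance(other, LineageTopology)
            and self.to_dict() == other.to_dict()
        )

    def __repr__(self):
        return (
            f"<LineageTopology {self.name!r}: {len(self.compartments)} compartments, "
            f"{len(self.edges)} edges>"
        )


def classify_edge_kind(src: Compartment, dst: Compartment) -> str:
    """Kind of a differentiation edge from compartment geometry."""
    dl = dst.level - src.level
    if dl == 0 and src.column != dst.column:
        return "horizontal"
    if dl >= 1:
        return "vertical" if src.column == dst.column else "diagonal"
    raise TopologyError(
        f"inadmissible edge {src.id}->{dst.id}: level must not decrease "
        f"and same-level edges must change column"
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _load_preset(name: str) -> dict:
    if name not in PRESET_NAMES:
        raise TopologyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    path = resources.files("lineageflux.presets").joinpath(name + ".json")
    return json.loads(path.read_text())


def build_possibility_graph(preset) -> LineageTopology:
    """Return the superposed graph of all admissible edges for a preset.

    ``preset`` is either a preset name (``"hsc_to_cmp_clp"``,
    ``"thrombopoiesis_full"``, ``"toy"``, ``"hsc_best"``) or a full
    topology specification dict following the topology JSON schema.
    """
    if isinstance(preset, dict):
        return LineageTopology.from_dict(preset)
    return LineageTopology.from_dict(_load_preset(preset)["topology"])


def preset_rules(name: str) -> EnumerationRules:
    """Enumeration rules shipped with a preset."""
    d = _load_preset(name)["rules"]
    return EnumerationRules(
        required_terminals=tuple(d["required_terminals"]),
        allow_reverse_column_change=d.get("allow_reverse_column_change", True),
        require_all_compartments_reachable=d.get(
            "require_all_compartments_reachable", True
        ),
        mandatory_edges=tuple(tuple(e) for e in d.get("mandatory_edges", [])),
        forbidden_edges=tuple(tuple(e) for e in d.get("forbidden_edges", [])),
    )


def preset_rates_dict(name: str) -> dict:
    """Raw default-rate dict of a preset (illustrative values)."""
    return _load_preset(name)["default_rates"]


# ---------------------------------------------------------------------------
# enumeration and classification
# ---------------------------------------------------------------------------


def _is_reverse_horizontal(t: LineageTopology, e: DifferentiationEdge) -> bool:
    if e.kind != "horizontal":
        return False
    src, dst = t.compartment(e.source), t.compartment(e.target)
    return t.column_rank(src.column) > t.column_rank(dst.column)


def enumerate_subtopologies(
    graph: LineageTopology, rules: EnumerationRules
) -> list[LineageTopology]:
    """Enumerate every admissible edge subset of a possibility graph.

    A subset is admissible when it contains all mandatory edges, no
    forbidden edges, makes every required terminal reachable from the
    tip, and (if required) makes every compartment reachable.  The full
    compartment roster is kept in every candidate; models differ only in
    their edge sets.  Output is deduplicated and ordered
    lexicographically by sorted edge list.
    """
    ids = set(graph.ids)
    for cid in rules.required_terminals:
        if cid not in ids:
            raise TopologyError(f"required terminal {cid!r} not in graph")
    all_keys = graph.edge_keys()
    mandatory = set(rules.mandatory_edges)
    forbidden = set(rules.forbidden_edges)
    for e in mandatory:
        if tuple(e) not in set(all_keys):
            raise TopologyError(f"mandatory edge {e} not in possibility graph")
    if mandatory & forbidden:
        raise TopologyError("an edge is both mandatory and forbidden")
    optional = []
    for e in graph.edges:
        k = e.key()
        if k in mandatory or k in forbidden:
            continue
        if not rules.allow_reverse_column_change and _is_reverse_horizontal(graph, e):
            continue
        optional.append(k)
    optional.sort()
    if len(optional) > 22:
        raise TopologyError(
            f"{len(optional)} optional edges exceed the exhaustive enumeration limit"
        )

    tip = graph.tip.id

    def admissible(edge_set: frozenset) -> bool:
        # reachability from the tip by BFS over the subset
        seen = {tip}
        frontier = [tip]
        succ: dict[str, list[str]] = {}
        for s, t in edge_set:
            succ.setdefault(s, []).append(t)
        while frontier:
            u = frontier.pop()
            for v in succ.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if any(term not in seen for term in rules.required_terminals):
            return False
        if rules.require_all_compartments_reachable and seen != ids:
            return False
        return True

    # feasibility: the maximal admissible edge set must itself satisfy the rules
    maximal = frozenset(mandatory) | frozenset(optional)
    if not admissible(maximal):
        raise TopologyError(
            "infeasible rules: required terminals or compartments unreachable "
            "even with every admissible edge present"
        )

    out: list[LineageTopology] = []
    seen_sets: set[frozenset] = set()
    n_opt = len(optional)
    for mask in range(1 << n_opt):
        edge_set = frozenset(mandatory) | frozenset(
            optional[i] for i in range(n_opt) if mask >> i & 1
        )
        if edge_set in seen_sets:
            continue
        seen_sets.add(edge_set)
        if admissible(edge_set):
            out.append(graph.with_edges(edge_set, require_reachable=False))
    out.sort(key=lambda t: t.edge_keys())
    return out


def classify_topology(t: LineageTopology) -> TopologyFeatures:
    """Classify a topology by the two model-space features.

    Parallel pathways: every marker column of the grid carries a
    complete vertical differentiation chain (edges linking all
    consecutive stages present in that column) and non-tip columns are
    entered from upstream.  Irreversible column loss: no horizontal edge
    moves against the column order (e.g. no Sca-1 lo -> hi reversion).
    """
    edge_set = set(t.edge_keys())
    marker_cols = [c for c in t.column_order if _is_marker_column(t, c)]
    parallel = True
    for col in marker_cols:
        comps = sorted(
            (c for c in t.compartments if c.column == col), key=lambda c: c.level
        )
        for a, b in itertools.pairwise(comps):
            if (a.id, b.id) not in edge_set:
                parallel = False
        if comps and not comps[0].is_tip:
            if not any(e.target == comps[0].id for e in t.edges):
                parallel = False
    irreversible = not any(_is_reverse_horizontal(t, e) for e in t.edges)
    return TopologyFeatures(
        parallel_pathways=parallel, irreversible_column_loss=irreversible
    )


def _is_marker_column(t: LineageTopology, col: str) -> bool:
    # marker columns are those holding the graded (level >= 1) chain structure;
    # auxiliary side columns (e.g. the Mk branch) with < 2 compartments or
    # outside the first two ranks do not enter the parallel-pathway feature
    comps = [c for c in t.compartments if c.column == col]
    return len(comps) >= 2 and t.column_rank(col) < 2
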