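"""Differentiation fluxes and pathway-origin probabilities.

The cell flux along an edge is the product of its differentiation rate
and the size of the source compartment, phi_ij = alpha_ij * N_i (cells
per day in the relative size units).  Pathway-origin probabilities
follow from composing incoming-flux weights backwards along each
tip-to-target path at demographic steady state: the probability that a
cell now in the target descended via a given path is the product over
the path's nodes of (flux of the edge used) / (total influx of that
node).  Proliferation within a node amplifies its output but does not
change any cell's ancestral path, so it cancels from the weights; this
definition is validated against the stochastic ancestry simulator
rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .topology import LineageTopology
from .odes import RateSet, assemble_odes, integrate, steady_state_sizes

__all__ = [
    "FluxReport",
    "PathwayDecomposition",
    "edge_fluxes",
    "pathway_probability",
    "pathway_share",
    "flux_ratio",
    "FluxRatio",
]


@dataclass
class FluxReport:
    """Per-edge cell fluxes and per-compartment budgets."""

    condition: str
    fluxes: dict[tuple[str, str], float]  # phi_ij = alpha_ij * N_i, per day
    production: dict[str, float]  # p_i * N_i
    loss: dict[str, float]  # delta_i * N_i
    sizes: dict[str, float]

    def influx(self, cid: str) -> float:
        return sum(v for (s, t), v in self.fluxes.items() if t == cid)

    def outflux(self, cid: str) -> float:
        return sum(v for (s, t), v in self.fluxes.items() if s == cid)

    def balance_residual(self, cid: str) -> float:
        """Relative steady-state balance: influx + net self-production - outflow - loss."""
        net = (self.influx(cid) + self.production.get(cid, 0.0)
               - self.outflux(cid) - self.loss.get(cid, 0.0))
        scale = max(self.influx(cid) + self.production.get(cid, 0.0), 1e-300)
        return net / scale

    def to_records(self) -> list[dict]:
        return [
            {"source": s, "target": t, "flux_per_day": v}
            for (s, t), v in sorted(self.fluxes.items())
        ]


@dataclass
class PathwayDecomposition:
    """All tip-to-target paths with their origin probabilities."""

    target: str
    paths: list[tuple[tuple[str, ...], float]]  # (compartment sequence, probability)

    def probability_of(self, path) -> float:
        path = tuple(path)
        for p, prob in self.paths:
            if p == path:
                return prob
        raise KeyError(f"path {path} not found")

    def total(self) -> float:
        return sum(p for _, p in self.paths)


def edge_fluxes(
    topology: LineageTopology,
    rates: RateSet,
    sizes: dict[str, float] | None = None,
    condition: str = "native",
    time_average: tuple[float, float] | None = None,
    n_grid: int = 101,
) -> FluxReport:
    """Per-edge fluxes phi_ij = alpha_ij * N_i with compartment budgets.

    ``sizes`` defaults to the rate set's N0 (use
    :func:`lineageflux.odes.steady_state_sizes` for the demographic
    steady state).  For non-stationary conditions, ``time_average``
    replaces each N_i by its mean over the given window, computed from
    the kinetic equations.
    """
    if time_average is not None:
        t0, t1 = time_average
        if not 0 <= t0 < t1:
            raise ValueError("time_average window must satisfy 0 <= t0 < t1")
        grid = np.linspace(0.0, t1, n_grid)
        traj = integrate(assemble_odes(topology, rates), grid)
        mask = grid >= t0
        sizes = {cid: float(np.mean(traj.N[mask, j]))
                 for j, cid in enumerate(traj.ids)}
    if sizes is None:
        sizes = dict(rates.N0)
    missing = [c.id for c in topology.compartments if c.id not in sizes]
    if missing:
        raise ValueError(f"missing sizes for compartments: {missing}")
    bad = {k: v for k, v in sizes.items() if not v > 0}
    if bad:
        raise ValueError(f"sizes must be positive, got {bad}")
    fluxes = {}
    for e in topology.edges:
        a = rates.alpha[e.key()]
        fluxes[e.key()] = a * sizes[e.source]
    production = {cid: rates.p.get(cid, 0.0) * sizes[cid] for cid in topology.ids}
    loss = {cid: rates.delta.get(cid, 0.0) * sizes[cid] for cid in topology.ids}
    return FluxReport(condition=condition, fluxes=fluxes, production=production,
                      loss=loss, sizes=dict(sizes))


def pathway_probability(
    topology: LineageTopology,
    rates: RateSet,
    sizes: dict[str, float] | None = None,
    target: str = "",
) -> PathwayDecomposition:
    """Probability that a target cell arose via each tip-to-target path.

    Requires an acyclic differentiation structure (reversible marker
    transitions create cycles; use the stochastic ancestry estimator for
    those).  Branch weights are incoming-flux fractions at steady state;
    a path's probability is the product of its branch weights.
    """
    if target not in set(topology.ids):
        raise ValueError(f"unknown target {target!r}")
    g = topology.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("topology contains cycles: use stochastic estimator "
                         "(simulate_stochastic ancestry frequencies)")
    tip = topology.tip.id
    if not nx.has_path(g, tip, target):
        raise ValueError(f"target {target!r} not reachable from tip {tip!r}")
    if sizes is None:
        ss = steady_state_sizes(topology, rates)
        if ss.diverged:
            raise ValueError("no stable steady state; provide sizes explicitly")
        sizes = ss.sizes
    fr = edge_fluxes(topology, rates, sizes)
    total_in = {cid: fr.influx(cid) for cid in topology.ids}
    paths = []
    for path in sorted(nx.all_simple_paths(g, tip, target)):
        w = 1.0
        for a, b in zip(path, path[1:]):
            denom = total_in[b]
            w *= fr.fluxes[(a, b)] / denom if denom > 0 else 0.0
        paths.append((tuple(path), w))
    total = sum(p for _, p in paths)
    if total <= 0:
        raise ValueError(f"no flux reaches target {target!r}")
    paths = [(p, w / total) for p, w in paths]
    return PathwayDecomposition(target=target, paths=paths)


@dataclass
class FluxRatio:
    """A flux ratio (or share) with percentile confidence bounds."""

    value: float
    lo: float | None = None
    hi: float | None = None
    unstable: bool = False
    undefined: bool = False


def pathway_share(
    report: FluxReport,
    target: str,
    grouping: dict[str, list[str]],
    band_reports: list[FluxReport] | None = None,
) -> dict[str, FluxRatio]:
    """Share of a target's influx carried by each group of source compartments.

    ``grouping`` partitions the sources of the target's incoming edges
    (e.g. direct vs conventional megakaryopoiesis routes).  Confidence
    bounds come from re-evaluating the shares over flux reports built
    from profile-likelihood band samples.
    """
    in_edges = [(s, t) for (s, t) in report.fluxes if t == target]
    if not in_edges:
        raise ValueError(f"target {target!r} has no incoming edges")
    sources = {s for s, _ in in_edges}
    grouped = [s for members in grouping.values() for s in members]
    if sorted(grouped) != sorted(sources):
        raise ValueError(
            f"grouping must partition the sources {sorted(sources)} of {target!r}, "
            f"got {sorted(grouped)}"
        )

    def shares(rep: FluxReport) -> dict[str, float] | None:
        total = sum(rep.fluxes[e] for e in in_edges)
        if total <= 0:
            return None
        return {
            gname: sum(rep.fluxes[(s, t)] for (s, t) in in_edges if s in members) / total
            for gname, members in grouping.items()
        }

    point = shares(report)
    out: dict[str, FluxRatio] = {}
    if point is None:
        return {g: FluxRatio(value=np.nan, undefined=True) for g in grouping}
    band_vals: dict[str, list[float]] = {g: [] for g in grouping}
    if band_reports:
        for rep in band_reports:
            sh = shares(rep)
            if sh is not None:
                for g, v in sh.items():
                    band_vals[g].append(v)
    for g, v in point.items():
        lo = hi = None
        if band_vals[g]:
            lo = float(np.percentile(band_vals[g], 2.5))
            hi = float(np.percentile(band_vals[g], 97.5))
        out[g] = FluxRatio(value=float(v), lo=lo, hi=hi)
    return out


def flux_ratio(
    report: FluxReport,
    numerator_edge: tuple[str, str],
    denominator_edge: tuple[str, str],
    band_reports: list[FluxReport] | None = None,
) -> FluxRatio:
    """Ratio of two edge fluxes with percentile confidence bounds.

    The point estimate requires a positive denominator flux; the
    interval is flagged unstable when the denominator vanishes in more
    than 5% of the band samples.
    """
    num = report.fluxes[tuple(numerator_edge)]
    den = report.fluxes[tuple(denominator_edge)]
    if den <= 0:
        raise ValueError(f"denominator flux {denominator_edge} is zero at the point estimate")
    value = num / den
    lo = hi = None
    unstable = False
    if band_reports:
        vals, n_zero = [], 0
        for rep in band_reports:
            d = rep.fluxes[tuple(denominator_edge)]
            if d <= 0:
                n_zero += 1
                continue
            vals.append(rep.fluxes[tuple(numerator_edge)] / d)
        if n_zero > 0.05 * len(band_reports):
            unstable = True
        if vals:
            lo = float(np.percentile(vals, 2.5))
            hi = float(np.percentile(vals, 97.5))
    return FluxRatio(value=float(value), lo=lo, hi=hi, unstable=unstable)
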