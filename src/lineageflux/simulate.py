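"""Synthetic cohorts and a stochastic ancestry-tracking oracle.

The experimental design being emulated is a pulse-chase fate-mapping
study: the heritable label is induced in tip stem cells at t = 0 with
mouse-to-mouse variability in the initial labelling frequency, and
groups of mice are sacrificed at staggered chase timepoints
(cross-sectional, not longitudinal).  Each mouse yields one bone-marrow
measurement per compartment and observable: RFP label fraction,
relative compartment size (fraction of lin- cells) and normalised
H2B-GFP retention.

The stochastic simulator implements the exact linear
birth-death-migration process whose expectations are the ODE system of
:mod:`lineageflux.odes`: division duplicates a cell and halves its GFP
register, differentiation moves it along an edge (appending to its
ancestry path), loss removes it.  It serves as an independent
agent-level oracle for the deterministic predictions and for
pathway-origin probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .topology import LineageTopology, build_possibility_graph, preset_rates_dict
from .odes import (
    RateSet,
    assemble_odes,
    integrate,
    predict_observables,
    steady_state_sizes,
)

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "ObservationTable",
    "AncestryRecord",
    "StochasticResult",
    "make_toy_model",
    "preset_model",
    "generate_cohort",
    "simulate_stochastic",
]

OBS_COLUMNS = ["condition", "mouse", "time_days", "compartment", "observable", "value", "sem", "n"]


@dataclass
class StudyDesign:
    """Cross-sectional chase design: which mice are sacrificed when."""

    timepoints: tuple[float, ...] = (3.0, 7.0, 14.0, 28.0, 56.0, 112.0, 168.0)
    mice_per_timepoint: int | tuple[int, ...] = 8
    conditions: tuple[str, ...] = ("native",)
    observables: tuple[str, ...] = ("label_fraction", "rel_size", "gfp_retention")
    compartments: tuple[str, ...] | None = None  # None = all observed
    seed: int = 0

    def __post_init__(self):
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) == 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", tps)
        m = self.mice_per_timepoint
        if isinstance(m, int):
            m = (m,) * len(tps)
        if len(m) != len(tps) or any(k < 1 for k in m):
            raise ValueError("need >= 1 mouse per timepoint")
        object.__setattr__(self, "mice_per_timepoint", tuple(m))


@dataclass
class NoiseModel:
    """Measurement noise applied to simulated observables.

    Label fractions receive binomial counting noise (``label_cells_counted``
    cells scored per sample) plus additive Gaussian noise of absolute SD
    ``label_sd``; relative sizes multiplicative lognormal noise of CV
    ``size_cv``; GFP retention additive Gaussian noise of SD ``gfp_sd``.
    ``tip_induction_cv`` is the mouse-to-mouse lognormal CV of the initial
    tip labelling frequency around the cohort mean.
    """

    label_sd: float = 0.02
    label_cells_counted: int | None = 500
    size_cv: float = 0.20
    gfp_sd: float = 0.05
    tip_induction_cv: float = 0.25

    def __post_init__(self):
        for name in ("label_sd", "size_cv", "gfp_sd", "tip_induction_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(label_sd=0.0, label_cells_counted=None, size_cv=0.0,
                   gfp_sd=0.0, tip_induction_cv=0.0)


class ObservationTable:
    """Tidy cross-sectional measurement table.

    One row per (condition, mouse, time, compartment, observable); the
    design is cross-sectional, so each mouse appears at exactly one
    bone-marrow timepoint.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        lab = self.df[self.df.observable.isin(["label_fraction", "label_fraction_normalized"])]
        if len(lab) and ((lab.value < 0).any() or
                         (lab[lab.observable == "label_fraction"].value > 1).any()):
            raise ValueError("label_fraction values must lie in [0, 1]")
        siz = self.df[self.df.observable == "rel_size"]
        if len(siz) and (siz.value <= 0).any():
            raise ValueError("rel_size values must be > 0")
        gfp = self.df[self.df.observable == "gfp_retention"]
        if len(gfp) and ((gfp.value <= 0).any() or (gfp.value > 1.05).any()):
            raise ValueError("gfp_retention values must lie in (0, 1.05]")
        per_mouse = self.df.groupby(["condition", "mouse"])["time_days"].nunique()
        if (per_mouse > 1).any():
            bad = per_mouse[per_mouse > 1].index.tolist()
            raise ValueError(f"cross-sectional design violated for mice {bad}")

    def aggregate(self) -> "ObservationTable":
        """Per-timepoint means with SEM over mice (the published fitting surface)."""
        g = self.df.groupby(["condition", "time_days", "compartment", "observable"])["value"]
        agg = g.agg(["mean", "sem", "count"]).reset_index()
        agg["mouse"] = "pooled"
        agg = agg.rename(columns={"mean": "value", "count": "n"})
        out = agg[["condition", "mouse", "time_days", "compartment", "observable",
                   "value", "sem", "n"]]
        return ObservationTable(out, validate=False)

    def subset(self, observables=None, conditions=None) -> "ObservationTable":
        df = self.df
        if observables is not None:
            df = df[df.observable.isin(observables)]
        if conditions is not None:
            df = df[df.condition.isin(conditions)]
        return ObservationTable(df.copy(), validate=False)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, ObservationTable) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# preset models
# ---------------------------------------------------------------------------


def _fill_steady_state(topology: LineageTopology, rates: RateSet) -> RateSet:
    ss = steady_state_sizes(topology, rates)
    if ss.diverged:
        raise ValueError("preset rates have no stable positive steady state")
    rates.N0 = {k: float(v) for k, v in ss.sizes.items()}
    return rates


def preset_model(name: str) -> tuple[LineageTopology, RateSet]:
    """Preset topology plus its default rates, sizes filled by flux balance."""
    topo = build_possibility_graph(name)
    rates = RateSet.from_dict(preset_rates_dict(name))
    return topo, _fill_steady_state(topo, rates)


def make_toy_model() -> tuple[LineageTopology, RateSet]:
    """The in-silico toy: a generic branching topology with known rates.

    Tip stem cells S (slow turnover, 0.015/day, demographically balanced)
    feed two parallel progenitor columns (A1, B1; turnover ~0.1-0.2/day)
    ending in two mature fates (A2, B2; turnover ~1/day).  One horizontal
    cross-edge (A1 -> B1) and one diagonal convergence edge (A1 -> B2)
    make compartment origins genuinely multi-pathway, so the candidate
    space of its subgraphs (9 models) exercises real model selection and
    the B2 fate receives cells by three distinct ancestral paths.
    Deterministic; sizes are the flux-balance steady state.
    """
    return preset_model("toy")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    topology: LineageTopology,
    rates: RateSet,
    design: StudyDesign,
    noise: NoiseModel,
    seed: int | None = None,
) -> ObservationTable:
    """Simulate a cross-sectional cohort of noisy measurements.

    Per mouse, the tip induction frequency is drawn around the cohort
    mean, the deterministic system is integrated, observables are read
    off at the mouse's sacrifice timepoint and measurement noise is
    applied.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    comp_ids = [c.id for c in topology.compartments if c.observed]
    if design.compartments is not None:
        unknown = set(design.compartments) - set(topology.ids)
        if unknown:
            raise ValueError(f"design requests unknown compartments: {sorted(unknown)}")
        unmeasured = [c for c in design.compartments
                      if not topology.compartment(c).observed]
        if unmeasured:
            raise ValueError(f"design requests unmeasured compartments: {unmeasured}")
        comp_ids = list(design.compartments)
    tip = topology.tip.id
    f0_mean = rates.f0.get(tip, 0.0)
    t_grid = np.concatenate([[0.0], np.asarray(design.timepoints)])

    rows = []
    for cond in design.conditions:
        for ti, n_mice in zip(design.timepoints, design.mice_per_timepoint):
            for m in range(n_mice):
                mouse = f"{cond}_d{ti:g}_m{m + 1}"
                r = _mouse_rates(rates, tip, f0_mean, noise, rng)
                system = assemble_odes(topology, r)
                traj = integrate(system, t_grid)
                pred = predict_observables(traj)
                k = int(np.searchsorted(t_grid, ti))
                for cid in comp_ids:
                    j = pred.ids.index(cid)
                    for kind in design.observables:
                        true = {"label_fraction": pred.f,
                                "rel_size": pred.s,
                                "gfp_retention": pred.g}[kind][k, j]
                        val = _apply_noise(true, kind, noise, rng)
                        rows.append((cond, mouse, ti, cid, kind, val, np.nan, 1))
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return ObservationTable(df)


def _mouse_rates(rates, tip, f0_mean, noise, rng) -> RateSet:
    f0 = dict(rates.f0)
    if noise.tip_induction_cv > 0 and f0_mean > 0:
        sig = np.sqrt(np.log1p(noise.tip_induction_cv ** 2))
        f0[tip] = min(1.0, f0_mean * np.exp(rng.normal(-0.5 * sig ** 2, sig)))
    return RateSet(alpha=rates.alpha, p=rates.p, delta=rates.delta,
                   N0=rates.N0, f0=f0, g0=rates.g0)


def _apply_noise(true: float, kind: str, noise: NoiseModel, rng) -> float:
    if kind == "label_fraction":
        v = float(true)
        if noise.label_cells_counted:
            v = rng.binomial(noise.label_cells_counted, min(max(v, 0.0), 1.0)) \
                / noise.label_cells_counted
        if noise.label_sd > 0:
            v += rng.normal(0.0, noise.label_sd)
        return float(np.clip(v, 0.0, 1.0))
    if kind == "rel_size":
        if noise.size_cv > 0:
            sig = np.sqrt(np.log1p(noise.size_cv ** 2))
            return float(true * np.exp(rng.normal(-0.5 * sig ** 2, sig)))
        return float(true)
    if kind == "gfp_retention":
        v = float(true)
        if noise.gfp_sd > 0:
            v += rng.normal(0.0, noise.gfp_sd)
        return float(np.clip(v, 1e-6, 1.05))
    raise ValueError(f"unknown observable kind {kind!r}")


# ---------------------------------------------------------------------------
# stochastic ancestry simulator
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class AncestryRecord:
    """Per-cell bookkeeping: where it is, how it got there, how often it divided.

    ``founder`` indexes the initial cell this cell descends from; founders
    evolve independently, so founder clusters give exact standard errors
    for any population summary from a single simulation.
    """

    compartment: str
    path: tuple[str, ...]
    divisions: int
    labeled: bool
    gfp: float
    founder: int


@dataclass
class StochasticResult:
    records: list[AncestryRecord]
    event_counts: Counter
    snapshots: dict | None = None  # time -> {"N": {...}, "L": {...}, "G": {...}}
    final_time: float = 0.0
    n_founders: int = 0


class _Buffered:
    """Buffered uniform/exponential draws (the event loop is RNG-bound)."""

    def __init__(self, rng, size=65536):
        self.rng, self.size = rng, size
        self._u = rng.random(size)
        self._e = rng.exponential(1.0, size)
        self._iu = self._ie = 0

    def u(self):
        if self._iu >= self.size:
            self._u = self.rng.random(self.size)
            self._iu = 0
        v = self._u[self._iu]
        self._iu += 1
        return v

    def e(self):
        if self._ie >= self.size:
            self._e = self.rng.exponential(1.0, self.size)
            self._ie = 0
        v = self._e[self._ie]
        self._ie += 1
        return v


def simulate_stochastic(
    topology: LineageTopology,
    rates: RateSet,
    n_cells: int,
    t_max: float,
    seed: int = 0,
    init: str = "tip",
    record_times=None,
    population_cap: int = 2_000_000,
) -> StochasticResult:
    """Exact event-driven simulation of the birth-death-migration process.

    Rates are interpreted exactly as in the ODE operator, so ensemble
    means of N, L and total GFP match the deterministic trajectories.
    ``init='tip'`` starts ``n_cells`` labelled-by-f0 cells at the tip;
    ``init='steady_state'`` populates every compartment at the
    flux-balance steady state scaled so the tip holds ``n_cells``.
    Division halves the continuous per-cell GFP register; differentiation
    appends the new compartment to the cell's ancestry path; loss removes
    the cell.  Aborts with a diagnostic if the population exceeds
    ``population_cap``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rates.validate(topology)
    rng = np.random.default_rng(seed)
    buf = _Buffered(rng)
    ids = topology.ids
    n_comp = len(ids)
    index = {cid: i for i, cid in enumerate(ids)}
    tip = index[topology.tip.id]

    # per-compartment event menu: [(rate, kind, target), ...]
    menus: list[list[tuple[float, str, int]]] = [[] for _ in range(n_comp)]
    for i, cid in enumerate(ids):
        p = rates.p.get(cid, 0.0)
        d = rates.delta.get(cid, 0.0)
        if p > 0:
            menus[i].append((p, "division", -1))
        if d > 0:
            menus[i].append((d, "loss", -1))
    for (s, t), a in rates.alpha.items():
        if a > 0:
            menus[index[s]].append((a, "differentiation", index[t]))
    comp_rate = [sum(r for r, _, _ in menu) for menu in menus]

    # cell state (grow-able arrays via python lists)
    comp_of: list[int] = []
    labeled: list[bool] = []
    gfp: list[float] = []
    divisions: list[int] = []
    path_of: list[int] = []
    founder_of: list[int] = []
    paths: list[tuple[str, ...]] = []
    path_index: dict[tuple[str, ...], int] = {}

    def intern(path: tuple[str, ...]) -> int:
        k = path_index.get(path)
        if k is None:
            k = len(paths)
            path_index[path] = k
            paths.append(path)
        return k

    members: list[list[int]] = [[] for _ in range(n_comp)]
    pos: list[int] = []

    def add_cell(ci, lab, g, dv, pid, fdr):
        cell = len(comp_of)
        comp_of.append(ci); labeled.append(lab); gfp.append(g)
        divisions.append(dv); path_of.append(pid); founder_of.append(fdr)
        pos.append(len(members[ci]))
        members[ci].append(cell)
        return cell

    def remove_cell(cell):
        ci = comp_of[cell]
        lst = members[ci]
        k = pos[cell]
        last = lst[-1]
        lst[k] = last
        pos[last] = k
        lst.pop()
        comp_of[cell] = -1

    f0_tip = rates.f0.get(ids[tip], 0.0)
    if init == "tip":
        n_lab = int(round(n_cells * f0_tip))
        for c in range(n_cells):
            add_cell(tip, c < n_lab, 1.0, 0, intern((ids[tip],)), c)
    elif init == "steady_state":
        ss = steady_state_sizes(topology, rates)
        if ss.diverged:
            raise ValueError("no stable steady state for steady_state init")
        scale = n_cells / ss.sizes[ids[tip]]
        for i, cid in enumerate(ids):
            count = int(round(ss.sizes[cid] * scale))
            f_i = rates.f0.get(cid, 0.0)
            n_lab = int(round(count * f_i))
            for c in range(count):
                add_cell(i, c < n_lab, 1.0, 0, intern((cid,)), len(comp_of))
    else:
        raise ValueError("init must be 'tip' or 'steady_state'")
    n_founders = len(comp_of)

    counts = [len(m) for m in members]
    weights = [counts[i] * comp_rate[i] for i in range(n_comp)]
    total = sum(weights)
    n_alive = sum(counts)

    rec_times = sorted(float(x) for x in record_times) if record_times else []
    snapshots: dict[float, dict] = {}

    def snap(tt):
        snapshots[tt] = {
            "N": {ids[i]: counts[i] for i in range(n_comp)},
            "L": {ids[i]: sum(1 for c in members[i] if labeled[c]) for i in range(n_comp)},
            "G": {ids[i]: float(sum(gfp[c] for c in members[i])) for i in range(n_comp)},
        }

    t = 0.0
    ev_counts: Counter = Counter()
    rec_i = 0
    while True:
        if total <= 0:
            break
        t_next = t + buf.e() / total
        while rec_i < len(rec_times) and rec_times[rec_i] <= min(t_next, t_max):
            snap(rec_times[rec_i])
            rec_i += 1
        if t_next > t_max:
            t = t_max
            break
        t = t_next
        # pick compartment
        u = buf.u() * total
        acc = 0.0
        ci = n_comp - 1
        for i in range(n_comp):
            acc += weights[i]
            if u <= acc:
                ci = i
                break
        if counts[ci] == 0:  # numerical drift in `total`; rebuild and retry
            total = sum(w for w in weights)
            continue
        # pick event
        v = buf.u() * comp_rate[ci]
        acc = 0.0
        rate, kind, target = menus[ci][-1]
        for r, kd, tg in menus[ci]:
            acc += r
            if v <= acc:
                kind, target = kd, tg
                break
        cell = members[ci][int(buf.u() * counts[ci])]
        ev_counts[(kind, ids[ci])] += 1
        if kind == "division":
            g = gfp[cell] * 0.5
            gfp[cell] = g
            divisions[cell] += 1
            add_cell(ci, labeled[cell], g, divisions[cell], path_of[cell],
                     founder_of[cell])
            counts[ci] += 1
            n_alive += 1
            if n_alive > population_cap:
                raise RuntimeError(
                    f"population exploded past cap {population_cap} at t={t:.2f} d; "
                    f"check for compartments with net growth (p > loss + outflow)"
                )
        elif kind == "loss":
            remove_cell(cell)
            counts[ci] -= 1
            n_alive -= 1
        else:  # differentiation
            remove_cell(cell)
            counts[ci] -= 1
            cj = target
            pid = intern(paths[path_of[cell]] + (ids[cj],))
            lab, g, dv = labeled[cell], gfp[cell], divisions[cell]
            add_cell(cj, lab, g, dv, pid, founder_of[cell])
            counts[cj] += 1
        weights[ci] = counts[ci] * comp_rate[ci]
        if kind == "differentiation":
            weights[target] = counts[target] * comp_rate[target]
        total = sum(weights)

    while rec_i < len(rec_times) and rec_times[rec_i] <= t_max:
        snap(rec_times[rec_i])
        rec_i += 1

    records = [
        AncestryRecord(
            compartment=ids[comp_of[c]],
            path=paths[path_of[c]],
            divisions=divisions[c],
            labeled=labeled[c],
            gfp=gfp[c],
            founder=founder_of[c],
        )
        for c in range(len(comp_of))
        if comp_of[c] >= 0
    ]
    return StochasticResult(
        records=records,
        event_counts=ev_counts,
        snapshots=snapshots or None,
        final_time=t,
        n_founders=n_founders,
    )
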