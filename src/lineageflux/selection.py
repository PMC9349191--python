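"""Model selection across candidate topologies.

Every candidate topology is fitted to the same observation table by
multistart maximum likelihood and ranked by the bias-corrected Akaike
information criterion; a single best model with a clear margin
(no competitor within dAICc < 2) is the selection outcome the
combined fate-mapping + mitotic-tracking + cell-number data are
expected to produce, while fate-mapping data alone typically leave
several topologies statistically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import LineageTopology, TopologyFeatures, classify_topology
from .model import (
    ErrorModel,
    FitConfig,
    LineageFitResults,
    LineageModel,
    aicc as _aicc,
)
from .simulate import ObservationTable

__all__ = [
    "ModelRanking",
    "rank_models",
    "ModelSelection",
    "StabilityReport",
    "subsample_stability",
    "MultiConditionResults",
    "multi_condition_fit",
]

_BANDS = ((0.0, "best"), (2.0, "strong"), (10.0, "acceptable"), (np.inf, "rejected"))


def _band(delta: float) -> str:
    if delta <= 0.0:
        return "best"
    if delta < 2.0:
        return "strong"
    if delta < 10.0:
        return "acceptable"
    return "rejected"


@dataclass
class ModelRanking:
    """Fits ordered by AICc with evidence bands and feature classes."""

    fits: list[LineageFitResults]
    features: list[TopologyFeatures]
    delta_aicc: np.ndarray
    bands: list[str]

    @property
    def winner(self) -> LineageFitResults:
        return self.fits[0]

    @property
    def winner_features(self) -> TopologyFeatures:
        return self.features[0]

    def margin(self) -> float:
        """dAICc of the runner-up (the winner's evidence margin)."""
        return float(self.delta_aicc[1]) if len(self.fits) > 1 else np.inf

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.class_label] = out.get(f.class_label, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit, feat, d, band in zip(self.fits, self.features, self.delta_aicc, self.bands):
            rows.append({
                "name": fit.topology_name,
                "n_edges": len(fit.model.topology.edges),
                "k": fit.k,
                "n": fit.n,
                "nll": fit.nll,
                "aicc": fit.aicc,
                "delta_aicc": d,
                "band": band,
                "class": feat.class_label,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Model ranking over {len(df)} candidate topologies "
                 f"(n = {self.fits[0].n} residuals each)"]
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.3f}"))
        counts = self.class_counts()
        lines.append("feature classes: " + ", ".join(f"{k}: {v}" for k, v in sorted(counts.items())))
        return "\n".join(lines)


def rank_models(
    fits: list[LineageFitResults],
    features: list[TopologyFeatures] | None = None,
) -> ModelRanking:
    """Order fits by AICc (ties: fewer parameters, then topology name)."""
    if not fits:
        raise ValueError("need at least one fit to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits have mixed residual counts {sorted(ns)}: "
                         "likelihoods are not comparable")
    if features is None:
        features = [classify_topology(f.model.topology) for f in fits]
    if len(features) != len(fits):
        raise ValueError("features and fits must align")
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aicc, fits[i].k, fits[i].topology_name))
    fits = [fits[i] for i in order]
    features = [features[i] for i in order]
    delta = np.array([f.aicc - fits[0].aicc for f in fits])
    bands = [_band(d) for d in delta]
    bands[0] = "best"
    return ModelRanking(fits=fits, features=features, delta_aicc=delta, bands=bands)


class ModelSelection:
    """Fit a set of candidate topologies to one dataset and rank them."""

    def __init__(
        self,
        topologies: list[LineageTopology],
        observations,
        error_model: ErrorModel | None = None,
        init: str = "steady_state",
    ):
        if not topologies:
            raise ValueError("need at least one candidate topology")
        self.topologies = list(topologies)
        self.observations = observations
        self.error_model = error_model
        self.init = init

    def fit_all(self, config: FitConfig | None = None) -> ModelRanking:
        cfg = config or FitConfig()
        fits = []
        for topo in self.topologies:
            m = LineageModel(topo, self.observations,
                             error_model=self.error_model, init=self.init)
            fits.append(m.fit(cfg))
        return rank_models(fits)


# ---------------------------------------------------------------------------
# subsampling robustness
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """How often the full-data winner survives data subsampling."""

    reference_winner: str
    reference_class: str
    winner_frequency: float
    class_frequency: float
    n_reps: int
    n_skipped: int
    winners: list[str] = field(default_factory=list)


def subsample_stability(
    topologies: list[LineageTopology],
    observations: ObservationTable,
    fraction: float = 0.5,
    reps: int = 20,
    seed: int = 0,
    config: FitConfig | None = None,
    error_model: ErrorModel | None = None,
    full_ranking: ModelRanking | None = None,
) -> StabilityReport:
    """Repeat model selection on stratified random subsets of the data.

    Rows of the per-mouse table are subsampled (without replacement)
    within strata defined by observable kind, timepoint and compartment,
    so every observable, chase time and compartment stays represented.  Subset refits
    warm-start from the full-data optimum of each topology (plus fresh
    Latin-hypercube starts), and the report gives the frequency with
    which the full-data winner, and its feature class, win again.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = config or FitConfig()
    if full_ranking is None:
        full_ranking = ModelSelection(
            topologies, observations, error_model=error_model
        ).fit_all(cfg)
    ref = full_ranking.winner.topology_name
    ref_class = full_ranking.winner_features.class_label
    warm = {f.topology_name: f.theta for f in full_ranking.fits}
    by_name = {t.name: t for t in topologies}

    rng = np.random.default_rng(seed)
    df = observations.df
    wins = class_wins = skipped = 0
    winners: list[str] = []
    for rep in range(reps):
        if fraction == 1.0:
            sub = df
        else:
            parts = []
            for _, g in df.groupby(["observable", "time_days", "compartment"], sort=True):
                m = max(1, int(round(fraction * len(g))))
                take = rng.choice(len(g), size=m, replace=False)
                parts.append(g.iloc[np.sort(take)])
            sub = pd.concat(parts).reset_index(drop=True)
        subtab = ObservationTable(sub, validate=False)
        fits = []
        try:
            for name, topo in by_name.items():
                mcfg = FitConfig(
                    n_starts=max(8, cfg.n_starts // 8),
                    seed=cfg.seed + 1000 * rep,
                    scan_max_nfev=cfg.scan_max_nfev,
                    n_polish=min(cfg.n_polish, 2),
                    polish_max_nfev=cfg.polish_max_nfev,
                    init=cfg.init,
                    extra_starts=(warm[name],),
                )
                m = LineageModel(topo, subtab, error_model=error_model, init=cfg.init)
                if m.nobs <= m.k_structural + 1:
                    raise _SkipRep
                fits.append(m.fit(mcfg))
            ranking = rank_models(fits)
        except _SkipRep:
            skipped += 1
            continue
        winners.append(ranking.winner.topology_name)
        if ranking.winner.topology_name == ref:
            wins += 1
        if ranking.winner_features.class_label == ref_class:
            class_wins += 1
    done = reps - skipped
    if done == 0:
        raise RuntimeError("all subsampling replicates were skipped (n <= k + 1)")
    return StabilityReport(
        reference_winner=ref,
        reference_class=ref_class,
        winner_frequency=wins / done,
        class_frequency=class_wins / done,
        n_reps=done,
        n_skipped=skipped,
        winners=winners,
    )


class _SkipRep(Exception):
    pass


# ---------------------------------------------------------------------------
# multi-condition fitting with parameter sharing
# ---------------------------------------------------------------------------


@dataclass
class MultiConditionResults:
    """Joint fit across conditions with tied parameters."""

    conditions: list[str]
    rates: dict[str, "RateSet"]  # per-condition point estimates
    nll: float
    k: int
    n: int
    aicc: float
    theta: np.ndarray
    param_names: list[str]  # joint layout: shared, then per-condition specific
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Multi-condition fit over {self.conditions}",
                 f"  NLL {self.nll:.4f}  k {self.k}  n {self.n}  AICc {self.aicc:.4f}"]
        for name, val in zip(self.param_names, 10.0 ** self.theta):
            lines.append(f"  {name:<28s} {val:.6g}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def multi_condition_fit(
    topology: LineageTopology,
    obs_by_condition: dict[str, ObservationTable],
    sharing: dict[str, str] | None = None,
    config: FitConfig | None = None,
    error_model: ErrorModel | None = None,
    init: str = "steady_state",
) -> MultiConditionResults:
    """Jointly fit one topology to several conditions with tied parameters.

    ``sharing`` maps parameter names (as in ``LineageModel.param_names``)
    to ``"shared"`` (one value across conditions, the default) or
    ``"specific"`` (one value per condition).  Condition-specific rates
    are what the flux comparisons between native and perturbed states
    (aging, thrombopoietin stimulation, myeloablation) are built on.
    """
    from scipy.optimize import least_squares
    from scipy.stats import qmc

    if not obs_by_condition:
        raise ValueError("need at least one condition")
    cfg = config or FitConfig()
    conditions = list(obs_by_condition)
    models = {
        c: LineageModel(topology, obs_by_condition[c], error_model=error_model, init=init)
        for c in conditions
    }
    base_names = models[conditions[0]].param_names
    sharing = dict(sharing or {})
    unknown = set(sharing) - set(base_names)
    if unknown:
        raise ValueError(f"sharing map references unknown parameters: {sorted(unknown)}")
    for v in sharing.values():
        if v not in ("shared", "specific"):
            raise ValueError("sharing values must be 'shared' or 'specific'")

    shared = [p for p in base_names if sharing.get(p, "shared") == "shared"]
    specific = [p for p in base_names if sharing.get(p, "shared") == "specific"]
    joint_names = list(shared) + [f"{p}[{c}]" for c in conditions for p in specific]

    # per-condition slices into the joint vector
    maps = {}
    for ci, c in enumerate(conditions):
        idx = np.empty(len(base_names), dtype=int)
        for bi, p in enumerate(base_names):
            if p in shared:
                idx[bi] = shared.index(p)
            else:
                idx[bi] = len(shared) + ci * len(specific) + specific.index(p)
        maps[c] = idx

    warns = []
    measured = set()
    for c in conditions:
        measured |= set(models[c].obs.df.compartment.unique())
    unmeasured = set(topology.ids) - measured
    if unmeasured:
        warns.append(f"compartments never measured in any condition: {sorted(unmeasured)}; "
                     "their rates may be unidentifiable")

    def residuals(theta):
        return np.concatenate([
            models[c].residuals(theta[maps[c]]) for c in conditions
        ])

    m0 = models[conditions[0]]
    lo_b, hi_b = m0.bounds(cfg)
    lo = np.concatenate([lo_b[[base_names.index(p) for p in shared]],
                         np.tile(lo_b[[base_names.index(p) for p in specific]], len(conditions))]) \
        if specific else lo_b[[base_names.index(p) for p in shared]]
    hi = np.concatenate([hi_b[[base_names.index(p) for p in shared]],
                         np.tile(hi_b[[base_names.index(p) for p in specific]], len(conditions))]) \
        if specific else hi_b[[base_names.index(p) for p in shared]]

    sampler = qmc.LatinHypercube(d=len(joint_names), seed=cfg.seed)
    starts = qmc.scale(sampler.random(cfg.n_starts), lo, hi)

    # warm starts from per-condition fits: shared entries from each single
    # condition's optimum (and their log-mean), specific entries per condition
    solo = {c: models[c].fit(cfg).theta for c in conditions}
    warm_rows = []
    pools = list(solo.values()) + [np.mean(list(solo.values()), axis=0)]
    for pool in pools:
        w = np.empty(len(joint_names))
        for si, p in enumerate(shared):
            w[si] = pool[base_names.index(p)]
        for ci, c in enumerate(conditions):
            for pi, p in enumerate(specific):
                w[len(shared) + ci * len(specific) + pi] = solo[c][base_names.index(p)]
        warm_rows.append(np.clip(w, lo, hi))
    starts = np.vstack([warm_rows, starts])
    best, best_cost = None, np.inf
    scans = []
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=cfg.scan_max_nfev,
                            xtol=1e-9, ftol=1e-9, gtol=1e-9)
        scans.append((float(sol.cost), sol.x))
    scans.sort(key=lambda t: t[0])
    for cost, x in scans[: cfg.n_polish]:
        sol = least_squares(residuals, x, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=cfg.polish_max_nfev,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if sol.cost < best_cost:
            best_cost, best = float(sol.cost), sol.x

    const = 0.0
    for c in conditions:
        s = models[c]._sigma
        if s is not None:
            const += float(np.sum(np.log(s)))
    nll = best_cost + const
    k = len(joint_names)
    n = sum(m.nobs for m in models.values())
    a = _aicc(nll, k, n) if n > k + 1 else np.inf
    rates = {c: models[c].rateset_from_theta(best[maps[c]]) for c in conditions}
    return MultiConditionResults(
        conditions=conditions, rates=rates, nll=nll, k=k, n=n, aicc=a,
        theta=best, param_names=joint_names, warnings=warns,
    )
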