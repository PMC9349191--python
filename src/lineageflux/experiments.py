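"""In-silico validation experiments.

Self-contained experiment runners that exercise the whole pipeline on
synthetic cohorts: candidate enumeration, model-selection recovery,
fate-mapping-only ambiguity, deterministic-vs-stochastic oracle checks,
pathway-probability validation, parameter recovery, profile-interval
coverage and data-subsampling robustness.  The test suite and the
reproduction script both run these; problem sizes are arguments so
that desk-scale runs stay cheap.

Stochastic comparisons use founder-cluster statistics: initial cells
evolve independently, so any population summary is a sum over iid
founder clusters and its standard error follows from the observed
cluster variance of a single simulation — no replicate runs or
distributional approximations needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import (
    build_possibility_graph,
    enumerate_subtopologies,
    preset_rules,
)
from .odes import assemble_odes, integrate, predict_observables
from .simulate import (
    NoiseModel,
    StudyDesign,
    generate_cohort,
    make_toy_model,
    preset_model,
    simulate_stochastic,
)
from .model import FitConfig, LineageModel, profile_ci
from .selection import ModelSelection, subsample_stability
from .fluxes import pathway_probability

__all__ = [
    "candidate_counts",
    "selection_experiment",
    "stochastic_oracle_check",
    "pathway_oracle_check",
    "noise_free_recovery",
    "coverage_experiment",
    "subsample_experiment",
    "toy_candidates",
]


def toy_candidates():
    return enumerate_subtopologies(build_possibility_graph("toy"),
                                   preset_rules("toy"))


def prepare_cohort(table, topology, observables=None):
    """The study's preprocessing: per-mouse label normalisation to the tip.

    Dividing each mouse's label fractions by its own tip labelling removes
    the mouse-to-mouse induction variability (which otherwise correlates
    all of a mouse's measurements and breaks the independent-Gaussian
    error model).  ``observables`` then optionally restricts the kinds
    ("label" selects the normalised label fractions).
    """
    from .io import normalize_to_reference

    out = normalize_to_reference(table, topology.tip.id)
    if observables is not None:
        kinds = ["label_fraction_normalized" if o in ("label", "label_fraction")
                 else o for o in observables]
        out = out.subset(observables=kinds)
    return out


def candidate_counts() -> dict[str, int]:
    """Size of the enumerated model space for the shipped presets."""
    out = {}
    for preset in ("hsc_to_cmp_clp", "toy"):
        subs = enumerate_subtopologies(build_possibility_graph(preset),
                                       preset_rules(preset))
        out[preset] = len(subs)
    return out


# ---------------------------------------------------------------------------
# model selection on toy cohorts
# ---------------------------------------------------------------------------


@dataclass
class SelectionOutcome:
    seed: int
    truth_first: bool
    margin: float  # dAICc of the runner-up when truth wins
    n_within_2: int  # topologies (incl. best) with dAICc < 2


def selection_experiment(
    n_cohorts: int = 10,
    seed: int = 0,
    observables: tuple[str, ...] | None = None,
    config: FitConfig | None = None,
) -> list[SelectionOutcome]:
    """Fit all toy candidates to seeded cohorts and record who wins.

    With all three observables the generating topology should rank first
    with a clear margin; with label fractions alone several candidates
    are expected to tie near the top.
    """
    topo, rates = make_toy_model()
    truth = topo.edge_hash()
    cands = toy_candidates()
    cfg = config or FitConfig()
    out = []
    for i in range(n_cohorts):
        cohort_seed = seed + 17 * i + 1
        tab = generate_cohort(topo, rates, StudyDesign(), NoiseModel(),
                              seed=cohort_seed)
        tab = prepare_cohort(tab, topo, observables)
        ranking = ModelSelection(cands, tab).fit_all(
            FitConfig(**{**cfg.__dict__, "seed": cfg.seed + i}))
        truth_first = ranking.winner.topology_name == truth
        if truth_first:
            margin = ranking.margin()
        else:
            names = [f.topology_name for f in ranking.fits]
            margin = -float(ranking.delta_aicc[names.index(truth)])
        out.append(SelectionOutcome(
            seed=cohort_seed,
            truth_first=truth_first,
            margin=margin,
            n_within_2=int(np.sum(ranking.delta_aicc < 2.0)),
        ))
    return out


# ---------------------------------------------------------------------------
# stochastic oracle checks
# ---------------------------------------------------------------------------


def _founder_cluster_stats(records, ids, n_founders):
    """Per-compartment (N, SE_N), (f, SE_f), (gbar, SE_g) from founder clusters."""
    idx = {cid: i for i, cid in enumerate(ids)}
    founders = {}
    for r in records:
        arr = founders.setdefault(r.founder, np.zeros((len(ids), 3)))
        i = idx[r.compartment]
        arr[i, 0] += 1
        arr[i, 1] += r.labeled
        arr[i, 2] += r.gfp
    F = n_founders
    stacked = np.zeros((F, len(ids), 3))
    for f, arr in founders.items():
        stacked[f] = arr
    out = {}
    for i, cid in enumerate(ids):
        n_c = stacked[:, i, 0]
        l_c = stacked[:, i, 1]
        g_c = stacked[:, i, 2]
        N = n_c.sum()
        se_N = np.sqrt(F * n_c.var(ddof=1))
        if N > 0:
            f_hat = l_c.sum() / N
            # delta method on the ratio of founder-cluster sums
            resid = l_c - f_hat * n_c
            se_f = np.sqrt(F * resid.var(ddof=1)) / N
            g_hat = g_c.sum() / N
            resid_g = g_c - g_hat * n_c
            se_g = np.sqrt(F * resid_g.var(ddof=1)) / N
        else:
            f_hat = se_f = g_hat = se_g = np.nan
        out[cid] = {"N": (N, se_N), "f": (f_hat, se_f), "g": (g_hat, se_g)}
    return out


def stochastic_oracle_check(
    preset: str,
    n_cells: int = 20_000,
    t_check: float = 40.0,
    seed: int = 0,
    min_cells: int = 50,
) -> dict:
    """Compare ODE predictions of N, f and mean GFP with the agent model.

    Starts ``n_cells`` at the tip and compares every compartment holding
    at least ``min_cells`` at the checkpoint.  Returns the z-scores
    (deviation over founder-cluster SE) per compartment and quantity.
    """
    from .odes import StateVector

    topo, rates = preset_model(preset)
    res = simulate_stochastic(topo, rates, n_cells, t_check, seed=seed,
                              init="tip")
    stats = _founder_cluster_stats(res.records, topo.ids, res.n_founders)
    # match the simulator's start: tip-only population, f0-labelled, g = 1
    sys_ = assemble_odes(topo, rates)
    tip_i = sys_.index[topo.tip.id]
    f0_tip = rates.f0.get(topo.tip.id, 0.0)
    n0 = np.zeros(len(topo.ids))
    n0[tip_i] = rates.N0[topo.tip.id]
    init = StateVector(N=n0, L=round(n_cells * f0_tip) / n_cells * n0, G=n0.copy())
    traj = integrate(sys_, np.array([0.0, t_check]), init)
    scale = n_cells / rates.N0[topo.tip.id]
    f0 = rates.f0.get(topo.tip.id, 0.0)
    zs = {}
    for j, cid in enumerate(topo.ids):
        N_ode = traj.N[1, j] * scale
        st = stats[cid]
        if not np.isfinite(st["N"][0]) or st["N"][0] < min_cells:
            continue
        entry = {}
        entry["N"] = (st["N"][0] - N_ode) / st["N"][1]
        if traj.N[1, j] > 0:
            f_ode = traj.L[1, j] / traj.N[1, j]
            g_ode = traj.G[1, j] / traj.N[1, j]
            if st["f"][1] > 0:
                entry["f"] = (st["f"][0] - f_ode) / st["f"][1]
            if st["g"][1] > 0:
                entry["g"] = (st["g"][0] - g_ode) / st["g"][1]
        zs[cid] = entry
    max_z = max(abs(v) for entry in zs.values() for v in entry.values())
    return {"preset": preset, "z": zs, "max_abs_z": float(max_z),
            "n_cells": n_cells, "initial_label": f0}


def pathway_oracle_check(
    n_founders: int = 60_000,
    t_check: float = 60.0,
    seed: int = 0,
    target: str = "B2",
) -> dict:
    """Flux-weight pathway probabilities vs ancestry frequencies.

    The toy's target fate receives cells via three distinct paths; their
    flux-composed probabilities are compared against the empirical path
    frequencies of the agent simulation (founder-cluster SEs).
    """
    topo, rates = make_toy_model()
    dec = pathway_probability(topo, rates, target=target)
    res = simulate_stochastic(topo, rates, n_founders, t_check, seed=seed,
                              init="tip")
    clusters: dict[int, dict[tuple, int]] = {}
    for r in res.records:
        if r.compartment == target:
            d = clusters.setdefault(r.founder, {})
            d[r.path] = d.get(r.path, 0) + 1
    F = res.n_founders
    total = sum(sum(d.values()) for d in clusters.values())
    zs = {}
    for path, prob in dec.paths:
        k_c = np.zeros(F)
        n_c = np.zeros(F)
        for f, d in clusters.items():
            k_c[f] = d.get(path, 0)
            n_c[f] = sum(d.values())
        emp = k_c.sum() / total
        resid = k_c - emp * n_c
        se = np.sqrt(F * resid.var(ddof=1)) / total
        zs[">".join(path)] = (emp - prob) / se if se > 0 else 0.0
    return {
        "target": target,
        "z": zs,
        "max_abs_z": float(max(abs(v) for v in zs.values())),
        "probability_sum": float(dec.total()),
        "n_target_cells": int(total),
    }


# ---------------------------------------------------------------------------
# recovery, coverage, subsampling
# ---------------------------------------------------------------------------


def _truth_theta(model: LineageModel, rates) -> np.ndarray:
    vals = []
    for name in model.param_names:
        kind, _, key = name.partition(":")
        if kind == "alpha":
            s, t = key.split(">")
            vals.append(rates.alpha[(s, t)])
        elif kind == "p":
            vals.append(rates.p[key])
        elif kind == "delta":
            vals.append(rates.delta[key])
        elif kind == "N0":
            vals.append(rates.N0[key])
        else:
            vals.append(rates.f0[key])
    return np.log10(vals)


def noise_free_recovery(seed: int = 0) -> dict:
    """Fit the generating topology to its own noise-free curves.

    Every rate is identifiable from the joint label/size/GFP surface, so
    the maximum relative parameter error measures optimizer quality.
    """
    from .model import ErrorModel

    topo, rates = make_toy_model()
    tab = generate_cohort(topo, rates, StudyDesign(mice_per_timepoint=1),
                          NoiseModel.zero(), seed=seed)
    em = ErrorModel(mode="fixed",
                    sigma={"label_fraction": 0.01, "rel_size": 0.05,
                           "gfp_retention": 0.01},
                    relative_kinds=("rel_size",))
    model = LineageModel(topo, tab, error_model=em)
    cfg = FitConfig(n_starts=64, seed=seed, scan_max_nfev=25, n_polish=3,
                    polish_max_nfev=1000)
    fit = model.fit(cfg)
    truth = 10.0 ** _truth_theta(model, rates)
    est = 10.0 ** fit.theta
    rel = np.abs(est / truth - 1.0)
    worst = int(np.argmax(rel))
    return {
        "max_rel_error": float(rel.max()),
        "worst_param": model.param_names[worst],
        "n_params": len(truth),
    }


def coverage_experiment(
    n_reps: int = 70,
    seed: int = 0,
    param: str = "alpha:S>A1",
    config: FitConfig | None = None,
) -> dict:
    """Profile-interval coverage of one rate over replicate noisy cohorts."""
    topo, rates = make_toy_model()
    kind, _, key = param.partition(":")
    s, t = key.split(">")
    true_val = rates.alpha[(s, t)]
    cfg = config or FitConfig()
    covered = 0
    for i in range(n_reps):
        tab = generate_cohort(topo, rates, StudyDesign(), NoiseModel(),
                              seed=seed + 101 * i + 3)
        tab = prepare_cohort(tab, topo)
        fit = LineageModel(topo, tab).fit(
            FitConfig(**{**cfg.__dict__, "seed": cfg.seed + i}))
        prof = profile_ci(fit, param)
        lo = 0.0 if prof.one_sided_lower else prof.ci[0]
        hi = np.inf if prof.one_sided_upper else prof.ci[1]
        if lo <= true_val <= hi:
            covered += 1
    return {"coverage": covered / n_reps, "n_reps": n_reps, "param": param,
            "true_value": true_val}


def subsample_experiment(
    reps: int = 20,
    fraction: float = 0.5,
    seed: int = 0,
    config: FitConfig | None = None,
) -> dict:
    """Half-data robustness of the toy selection winner."""
    topo, rates = make_toy_model()
    cands = toy_candidates()
    cfg = config or FitConfig()
    tab = generate_cohort(topo, rates, StudyDesign(), NoiseModel(),
                          seed=seed + 7)
    tab = prepare_cohort(tab, topo)
    full = ModelSelection(cands, tab).fit_all(cfg)
    rep = subsample_stability(cands, tab, fraction=fraction, reps=reps,
                              seed=seed, config=cfg, full_ranking=full)
    return {
        "winner_frequency": rep.winner_frequency,
        "class_frequency": rep.class_frequency,
        "full_winner_is_truth": full.winner.topology_name == topo.edge_hash(),
        "n_reps": rep.n_reps,
    }
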