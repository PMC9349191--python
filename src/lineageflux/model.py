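"""Maximum-likelihood fitting of lineage kinetic models.

The central objects follow the Model/Results convention: a
:class:`LineageModel` binds one candidate topology to an observation
table and an error model; its :meth:`~LineageModel.fit` runs multistart
trust-region minimisation of the Gaussian negative log-likelihood
(initial points by Latin hypercube sampling in log10-parameter space)
and returns a :class:`LineageFitResults` carrying the estimates, NLL,
free-parameter count, AICc and diagnostics.  Profile-likelihood
confidence intervals and prediction-band samples hang off the results
object.

By default parameters are the differentiation rates (one per edge),
proliferation rates (non-tip compartments that allow it), loss rates
(compartments that allow it), the tip size and the tip induction
frequency; compartment sizes are tied to the demographic steady state
(tip fixed, flux balance downstream), which is how fits to native,
unperturbed hematopoiesis are initialised.  ``init='free'`` releases
all initial sizes and the tip proliferation rate for non-stationary
conditions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .topology import LineageTopology
from .odes import RateSet, OBSERVABLE_KINDS, matrix_exponential
from .simulate import ObservationTable

__all__ = [
    "ErrorModel",
    "FitConfig",
    "LineageModel",
    "LineageFitResults",
    "ProfileResult",
    "aicc",
    "negative_log_likelihood",
    "fit_model",
    "profile_ci",
]

log = logging.getLogger(__name__)

# the fourth kind is the study's per-mouse normalisation: each mouse's label
# fractions divided by its tip labelling, in which the induction level cancels
_ALL_KINDS = OBSERVABLE_KINDS + ("label_fraction_normalized",)
_KIND_INDEX = {k: i for i, k in enumerate(_ALL_KINDS)}
_PENALTY = 1e4


def aicc(nll: float, k: int, n: int) -> float:
    """Bias-corrected Akaike information criterion.

    AICc = 2k + 2 NLL + 2k(k+1)/(n - k - 1); defined only for n > k + 1.
    """
    if k < 0 or n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return 2.0 * k + 2.0 * nll + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ErrorModel:
    """Gaussian error model for the NLL.

    ``use_reported_sem`` (default) takes each observation's reported SEM
    as its sigma — weighted least squares on the published mean +/- SEM
    curves.  ``fixed`` uses user-supplied per-observable sigmas
    (``relative_kinds`` entries are scaled by |y|).  ``fitted_constant``
    profiles one constant sigma per observable kind out of the
    likelihood analytically; those sigmas count as free parameters.
    """

    mode: str = "use_reported_sem"
    sigma: dict = field(default_factory=dict)
    relative_kinds: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("use_reported_sem", "fixed", "fitted_constant"):
            raise ValueError(f"unknown error-model mode {self.mode!r}")


@dataclass
class FitConfig:
    """Multistart optimisation schedule.

    ``n_starts`` Latin-hypercube starts are each refined by a
    trust-region pass with a bounded evaluation budget; the best
    ``n_polish`` are then polished to tight tolerance.  Bounds are in
    log10 space (rates per day).
    """

    n_starts: int = 64
    seed: int = 0
    rate_bounds: tuple[float, float] = (-4.0, 1.0)
    size_bounds: tuple[float, float] = (-5.0, 0.0)
    f0_bounds: tuple[float, float] = (-3.0, 0.0)
    scan_max_nfev: int = 12
    n_polish: int = 2
    polish_max_nfev: int = 400
    init: str = "steady_state"  # or "free"
    extra_starts: tuple = ()

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for lo, hi in (self.rate_bounds, self.size_bounds, self.f0_bounds):
            if not lo < hi:
                raise ValueError("lower bound must be below upper bound")


# ---------------------------------------------------------------------------
# fast linear-kinetics evaluator
# ---------------------------------------------------------------------------

_small_expm = matrix_exponential


class _FastKinetics:
    """Vectorised prediction of (f, s, g) on a fixed time grid.

    Exploits linearity: the operator is eigendecomposed once per
    parameter vector and applied to all timepoints at once, with an
    ``expm`` fallback near defective spectra and exponent clipping so
    that wild multistart draws yield large finite residuals rather than
    overflow.
    """

    def __init__(self, topology: LineageTopology, t_grid: np.ndarray):
        self.ids = topology.ids
        self.n = len(self.ids)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self.t_grid = np.asarray(t_grid, dtype=float)
        self.edge_keys = topology.edge_keys()
        self.src = np.array([self.index[s] for s, _ in self.edge_keys], dtype=int)
        self.dst = np.array([self.index[t] for _, t in self.edge_keys], dtype=int)
        self.tip = self.index[topology.tip.id]

    def operator(self, alpha: np.ndarray, p: np.ndarray, delta: np.ndarray):
        n = self.n
        A = np.zeros((n, n))
        np.add.at(A, (self.dst, self.src), alpha)
        out = np.zeros(n)
        np.add.at(out, self.src, alpha)
        A[np.diag_indices(n)] += p - delta - out
        return A

    @staticmethod
    def _eig_apply(A, t_grid, X0):
        try:
            lam, V = np.linalg.eig(A)
            cond = np.linalg.cond(V)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(cond) or cond >= 1e8:
            return None
        C = np.linalg.solve(V, X0)  # (n, ncols)
        Z = np.outer(t_grid, lam)
        Z = np.clip(Z.real, None, 60.0) + 1j * Z.imag
        E = np.exp(Z)  # (T, n)
        return np.einsum("ij,tj,jc->tic", V, E, C).real

    @staticmethod
    def _apply(A, t_grid, X0):
        """exp(A t) @ x0 for each column of X0, stacked as (T, n, ncols).

        Spectral path when the eigenbasis is well conditioned; defective
        spectra (repeated net turnover across compartments) fall back to
        stepping scaling-and-squaring matrix exponentials, which are
        exact for the linear system.
        """
        if X0.ndim == 1:
            X0 = X0[:, None]
        out = _FastKinetics._eig_apply(A, t_grid, X0)
        if out is not None:
            return out
        n = A.shape[0]
        res = np.empty((len(t_grid), n, X0.shape[1]))
        x = X0
        t_prev = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for i, ti in enumerate(t_grid):
                if ti > t_prev:
                    x = _small_expm(A * (ti - t_prev)) @ x
                    x = np.nan_to_num(x, nan=0.0, posinf=1e26, neginf=-1e26)
                    t_prev = ti
                res[i] = x
        return res

    def steady_state(self, A, n0_tip):
        idx = [i for i in range(self.n) if i != self.tip]
        if not idx:
            return np.array([n0_tip]), -np.inf
        Ann = A[np.ix_(idx, idx)]
        lam_max = float(np.max(np.linalg.eigvals(Ann).real))
        if lam_max >= 0:
            return None, lam_max
        try:
            x = np.linalg.solve(Ann, -A[idx, self.tip] * n0_tip)
        except np.linalg.LinAlgError:
            return None, lam_max
        if np.any(x <= 0):
            return None, lam_max
        N0 = np.empty(self.n)
        N0[self.tip] = n0_tip
        N0[idx] = x
        return N0, lam_max

    def predict(self, alpha, p, delta, N0, f0_vec):
        """Return (f, s, g) arrays of shape (T, n), or (None, penalty)."""
        A = self.operator(alpha, p, delta)
        L0 = f0_vec * N0
        G0 = N0.copy()
        X = self._apply(A, self.t_grid, np.column_stack([N0, L0]))
        N, L = X[:, :, 0], X[:, :, 1]
        G = self._apply(A - np.diag(p), self.t_grid, G0[:, None])[:, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            safe = np.where(np.abs(N) > 1e-300, N, 1.0)
            f = np.where(N > 0, L / safe, np.nan)
            g = np.where(N > 0, (G / safe) / 1.0, np.nan)
        return f, N, g


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------


class LineageModel:
    """One candidate topology bound to an observation table.

    Parameters
    ----------
    topology : LineageTopology
    observations : ObservationTable or DataFrame
        Per-mouse rows are aggregated to per-timepoint means with SEM
        (the published fitting surface) unless ``aggregate=False``.
    error_model : ErrorModel, optional
    init : {"steady_state", "free"}
        Size treatment; see module docstring.
    """

    def __init__(
        self,
        topology: LineageTopology,
        observations,
        error_model: ErrorModel | None = None,
        aggregate: bool = True,
        init: str = "steady_state",
    ):
        if isinstance(observations, pd.DataFrame):
            observations = ObservationTable(observations, validate=False)
        if len(observations) == 0:
            raise ValueError("observation table is empty")
        self.topology = topology
        self.error_model = error_model or ErrorModel()
        self.init = init
        if init not in ("steady_state", "free"):
            raise ValueError("init must be 'steady_state' or 'free'")
        obs = observations
        if aggregate and not (obs.df["mouse"] == "pooled").all():
            obs = obs.aggregate()
        self.obs = obs
        df = obs.df
        unknown = set(df.compartment) - set(topology.ids)
        if unknown:
            raise ValueError(f"observations reference unknown compartments: {sorted(unknown)}")
        bad_kind = set(df.observable) - set(_ALL_KINDS)
        if bad_kind:
            raise ValueError(f"unknown observable kinds: {sorted(bad_kind)}")
        self._has_raw_label = "label_fraction" in set(df.observable)

        times = np.unique(df.time_days.to_numpy(dtype=float))
        self.t_grid = np.concatenate([[0.0], times]) if times[0] > 0 else times
        self._kin = _FastKinetics(topology, self.t_grid)
        t_pos = {t: i for i, t in enumerate(self.t_grid)}
        self._row_t = df.time_days.map(t_pos).to_numpy(dtype=int)
        self._row_c = df.compartment.map(self._kin.index).to_numpy(dtype=int)
        self._row_k = df.observable.map(_KIND_INDEX).to_numpy(dtype=int)
        self._y = df.value.to_numpy(dtype=float)
        self.nobs = len(self._y)
        self._sigma = self._sigmas_from_error_model(df)
        if self._sigma is not None:
            keep = np.isfinite(self._sigma) & (self._sigma > 1e-8)
            if not keep.all():
                n_drop = int((~keep).sum())
                log.info(
                    "dropping %d observations with zero/degenerate SEM "
                    "(uninformative rows, e.g. the normalised reference "
                    "compartment or replicates at a detection floor)", n_drop)
                self._row_t = self._row_t[keep]
                self._row_c = self._row_c[keep]
                self._row_k = self._row_k[keep]
                self._y = self._y[keep]
                self._sigma = self._sigma[keep]
                self.nobs = int(keep.sum())
            if self.nobs == 0:
                raise ValueError("no observations with usable SEM remain")
        self._build_parameters()

    # -- error model ----------------------------------------------------------

    def _sigmas_from_error_model(self, df) -> np.ndarray | None:
        e = self.error_model
        if e.mode == "use_reported_sem":
            s = df["sem"].to_numpy(dtype=float)
            if not np.isfinite(s).any() or np.nanmax(s) <= 0:
                raise ValueError(
                    "use_reported_sem requires reported SEMs; "
                    "use the 'fixed' or 'fitted_constant' error model otherwise"
                )
            return s
        if e.mode == "fixed":
            s = np.empty(self.nobs)
            for kind, ki in _KIND_INDEX.items():
                m = self._row_k == ki
                if not m.any():
                    continue
                if kind not in e.sigma:
                    raise ValueError(f"fixed error model missing sigma for {kind!r}")
                val = float(e.sigma[kind])
                if val <= 0:
                    raise ValueError("sigma must be > 0")
                s[m] = val * np.abs(self._y[m]) if kind in e.relative_kinds else val
            if np.any(s <= 0):
                raise ValueError("fixed relative sigma hit a zero observation")
            return s
        return None  # fitted_constant: sigmas are profiled during fit

    # -- parameter layout -----------------------------------------------------

    def _build_parameters(self):
        t = self.topology
        names: list[str] = []
        self._edge_slice = slice(0, len(self._kin.edge_keys))
        names += [f"alpha:{s}>{d}" for s, d in self._kin.edge_keys]
        tip_id = t.tip.id
        self._p_ids = [
            c.id
            for c in t.compartments
            if c.allows_proliferation and (self.init == "free" or not c.is_tip)
        ]
        names += [f"p:{c}" for c in self._p_ids]
        self._d_ids = [c.id for c in t.compartments if c.allows_loss]
        names += [f"delta:{c}" for c in self._d_ids]
        if self.init == "steady_state":
            self._n0_ids = [tip_id]
        else:
            self._n0_ids = list(t.ids)
        names += [f"N0:{c}" for c in self._n0_ids]
        # with only normalised label data the induction level cancels out
        self._f0_ids = [tip_id] if self._has_raw_label else []
        names += [f"f0:{c}" for c in self._f0_ids]
        self.param_names = names
        self.k_structural = len(names)

    def bounds(self, cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.param_names:
            kind = name.split(":", 1)[0]
            b = {"alpha": cfg.rate_bounds, "p": cfg.rate_bounds,
                 "delta": cfg.rate_bounds, "N0": cfg.size_bounds,
                 "f0": cfg.f0_bounds}[kind]
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def _decode(self, theta: np.ndarray):
        v = 10.0 ** np.asarray(theta, dtype=float)
        ne = len(self._kin.edge_keys)
        alpha = v[:ne]
        pos = ne
        p = np.zeros(self._kin.n)
        for cid in self._p_ids:
            p[self._kin.index[cid]] = v[pos]
            pos += 1
        delta = np.zeros(self._kin.n)
        for cid in self._d_ids:
            delta[self._kin.index[cid]] = v[pos]
            pos += 1
        n0 = np.zeros(self._kin.n)
        for cid in self._n0_ids:
            n0[self._kin.index[cid]] = v[pos]
            pos += 1
        f0 = np.zeros(self._kin.n)
        for cid in self._f0_ids:
            f0[self._kin.index[cid]] = v[pos]
            pos += 1
        if not self._f0_ids:
            f0[self._kin.tip] = 0.5  # arbitrary; cancels in normalised fractions
        if self.init == "steady_state":
            # tip demographic balance: proliferation replaces outflow + loss
            tip = self._kin.tip
            out = float(alpha[self._kin.src == tip].sum())
            p[tip] = out + delta[tip]
        return alpha, p, delta, n0, f0

    def rateset_from_theta(self, theta: np.ndarray) -> RateSet:
        alpha, p, delta, n0, f0 = self._decode(theta)
        kin = self._kin
        if self.init == "steady_state":
            A = kin.operator(alpha, p, delta)
            N0, _ = kin.steady_state(A, n0[kin.tip])
            if N0 is None:
                N0 = n0
        else:
            N0 = n0
        return RateSet(
            alpha={e: float(a) for e, a in zip(kin.edge_keys, alpha)},
            p={cid: float(p[kin.index[cid]]) for cid in kin.ids},
            delta={cid: float(delta[kin.index[cid]]) for cid in kin.ids
                   if delta[kin.index[cid]] > 0},
            N0={cid: float(N0[kin.index[cid]]) for cid in kin.ids},
            f0={cid: float(f0[kin.index[cid]]) for cid in kin.ids
                if f0[kin.index[cid]] > 0},
        )

    # -- objective ------------------------------------------------------------

    def _predict_rows(self, theta: np.ndarray):
        alpha, p, delta, n0, f0 = self._decode(theta)
        kin = self._kin
        if self.init == "steady_state":
            A = kin.operator(alpha, p, delta)
            N0, lam = kin.steady_state(A, n0[kin.tip])
            if N0 is None:
                return None, lam
        else:
            N0 = n0
        f, s, g = kin.predict(alpha, p, delta, N0, f0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_tip = f[:, kin.tip]
            f_norm = f / np.where(f_tip > 0, f_tip, np.nan)[:, None]
        stack = np.stack([f, s, g, f_norm])  # (kind, T, comp)
        return stack[self._row_k, self._row_t, self._row_c], 0.0

    def residuals(self, theta: np.ndarray, sigma: np.ndarray | None = None) -> np.ndarray:
        if sigma is None:
            sigma = self._sigma
            if sigma is None:  # fitted_constant outside fit(): unit weights
                sigma = np.ones(self.nobs)
        pred, lam = self._predict_rows(theta)
        if pred is None:
            return np.full(self.nobs, _PENALTY * (1.0 + min(lam, 10.0)))
        r = (pred - self._y) / sigma
        bad = ~np.isfinite(r)
        if bad.any():
            r = np.where(bad, _PENALTY, r)
        return np.clip(r, -1e12, 1e12)

    def nll(self, theta: np.ndarray, sigma: np.ndarray | None = None) -> float:
        if sigma is None and self._sigma is not None:
            sigma = self._sigma
        r = self.residuals(theta, sigma)
        const = float(np.sum(np.log(sigma))) if sigma is not None else 0.0
        return 0.5 * float(np.sum(r * r)) + const

    # -- fitting --------------------------------------------------------------

    def fit(self, config: FitConfig | None = None) -> "LineageFitResults":
        cfg = config or FitConfig()
        lo, hi = self.bounds(cfg)
        kdim = len(self.param_names)
        sampler = qmc.LatinHypercube(d=kdim, seed=cfg.seed)
        starts = qmc.scale(sampler.random(cfg.n_starts), lo, hi)
        extra = [np.clip(np.asarray(e, dtype=float), lo, hi) for e in cfg.extra_starts]
        starts = np.vstack([np.array(extra), starts]) if extra else starts

        sigma = self._sigma
        fitted_sigma: dict[str, float] | None = None
        if self.error_model.mode == "fitted_constant":
            sigma = self._initial_sigma_guess()

        theta_best, trace = self._multistart(starts, lo, hi, sigma, cfg)

        if self.error_model.mode == "fitted_constant":
            for _ in range(3):  # concentrate sigma out, then re-polish
                fitted_sigma = self._profiled_sigma(theta_best)
                sigma = self._sigma_vector(fitted_sigma)
                theta_best = self._polish(theta_best, lo, hi, sigma, cfg.polish_max_nfev)

        nll = self.nll(theta_best, sigma)
        k = self.k_structural + (len(fitted_sigma) if fitted_sigma else 0)
        n = self.nobs
        if n > k + 1:
            a = aicc(nll, k, n)
        else:
            warnings.warn(f"AICc undefined at n={n}, k={k}; reporting +inf")
            a = math.inf
        return LineageFitResults(
            model=self,
            config=cfg,
            theta=theta_best,
            nll=nll,
            k=k,
            n=n,
            aicc=a,
            per_start_nll=trace,
            sigma=None if sigma is None else np.asarray(sigma),
            fitted_sigma=fitted_sigma,
        )

    def _initial_sigma_guess(self) -> np.ndarray:
        s = np.empty(self.nobs)
        for ki in np.unique(self._row_k):
            m = self._row_k == ki
            sd = float(np.std(self._y[m]))
            s[m] = max(sd, 1e-6)
        return s

    def _profiled_sigma(self, theta) -> dict[str, float]:
        pred, _ = self._predict_rows(theta)
        if pred is None:
            return {k: 1.0 for k in OBSERVABLE_KINDS}
        out = {}
        for kind, ki in _KIND_INDEX.items():
            m = self._row_k == ki
            if m.any():
                out[kind] = max(float(np.sqrt(np.mean((pred[m] - self._y[m]) ** 2))), 1e-9)
        return out

    def _sigma_vector(self, per_kind: dict[str, float]) -> np.ndarray:
        s = np.ones(self.nobs)
        for kind, val in per_kind.items():
            s[self._row_k == _KIND_INDEX[kind]] = val
        return s

    def _multistart(self, starts, lo, hi, sigma, cfg):
        results = []
        for x0 in starts:
            try:
                sol = least_squares(
                    self.residuals, x0, args=(sigma,), bounds=(lo, hi),
                    method="trf", x_scale="jac", max_nfev=cfg.scan_max_nfev,
                    xtol=1e-9, ftol=1e-9, gtol=1e-9,
                )
                results.append((float(sol.cost), sol.x))
            except Exception as err:  # pragma: no cover - defensive
                log.debug("start failed: %s", err)
                results.append((math.inf, x0))
        if all(not math.isfinite(c) for c, _ in results):
            raise RuntimeError("all multistart optimisations failed; trace: "
                               + ", ".join(f"{c:.3g}" for c, _ in results))
        order = np.argsort([c for c, _ in results], kind="stable")
        best_theta, best_cost = None, math.inf
        for i in order[: cfg.n_polish]:
            th = self._polish(results[i][1], lo, hi, sigma, cfg.polish_max_nfev)
            c = 0.5 * float(np.sum(self.residuals(th, sigma) ** 2))
            if c < best_cost:
                best_cost, best_theta = c, th
        const = float(np.sum(np.log(sigma))) if sigma is not None else 0.0
        trace = np.array([c + const if math.isfinite(c) else math.inf
                          for c, _ in results])
        return best_theta, trace

    def _polish(self, x0, lo, hi, sigma, max_nfev):
        sol = least_squares(
            self.residuals, np.clip(x0, lo, hi), args=(sigma,), bounds=(lo, hi),
            method="trf", x_scale="jac", max_nfev=max_nfev,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        return sol.x


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter."""

    param: str
    grid: np.ndarray  # (m, 2): parameter value (natural units), profiled NLL
    ci: tuple[float, float]
    level: float
    one_sided_lower: bool
    one_sided_upper: bool
    band_thetas: np.ndarray  # full parameter vectors with dNLL <= threshold


@dataclass
class LineageFitResults:
    """Estimates and diagnostics for one topology on one dataset."""

    model: LineageModel
    config: FitConfig
    theta: np.ndarray
    nll: float
    k: int
    n: int
    aicc: float
    per_start_nll: np.ndarray
    sigma: np.ndarray | None = None
    fitted_sigma: dict | None = None

    @property
    def topology_name(self) -> str:
        return self.model.topology.name

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, 10.0 ** self.theta))

    @property
    def rates(self) -> RateSet:
        return self.model.rateset_from_theta(self.theta)

    @property
    def converged(self) -> bool:
        return bool(np.isfinite(self.nll))

    def predict(self, t_grid=None):
        """Model observables on a time grid (defaults to the data grid)."""
        from .odes import assemble_odes, integrate, predict_observables

        rs = self.rates
        t = self.model.t_grid if t_grid is None else np.asarray(t_grid, dtype=float)
        traj = integrate(assemble_odes(self.model.topology, rs), t)
        return predict_observables(traj)

    def profile(self, param: str, level: float = 0.95, **kw) -> ProfileResult:
        return profile_ci(self, param, level=level, **kw)

    def summary(self) -> str:
        lines = [
            f"LineageFitResults: topology {self.topology_name}",
            f"  NLL {self.nll:.4f}   k {self.k}   n {self.n}   AICc {self.aicc:.4f}",
            f"  starts {len(self.per_start_nll)} (best-of-starts contract: "
            f"{np.nanmin(self.per_start_nll) >= self.nll - 1e-6})",
            "  parameter            estimate",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<20s} {val:.6g}")
        if self.fitted_sigma:
            for kind, s in self.fitted_sigma.items():
                lines.append(f"  sigma[{kind}]   {s:.6g}")
        return "\n".join(lines)

    def plot_fit(self, path=None):
        """Diagnostic plot: data (mean +/- SEM) with fitted curves."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.model.obs.df
        tmax = float(df.time_days.max())
        grid = np.linspace(0.0, tmax, 80)
        pred = self.predict(grid)
        kinds = sorted(df.observable.unique())
        fig, axes = plt.subplots(1, len(kinds), figsize=(4 * len(kinds), 3.2))
        axes = np.atleast_1d(axes)
        for ax, kind in zip(axes, kinds):
            sub = df[df.observable == kind]
            tip_id = self.model.topology.tip.id
            for cid, gdf in sub.groupby("compartment"):
                if kind == "label_fraction_normalized":
                    curve = (pred.lookup(cid, "label_fraction")
                             / pred.lookup(tip_id, "label_fraction"))
                else:
                    curve = pred.lookup(cid, kind)
                (line,) = ax.plot(grid, curve, lw=1.2, label=cid)
                ax.errorbar(gdf.time_days, gdf.value, yerr=gdf["sem"], fmt="o",
                            ms=3, color=line.get_color(), alpha=0.7)
            ax.set_title(kind)
            ax.set_xlabel("days of chase")
            if kind == "rel_size":
                ax.set_yscale("log")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def to_report_dict(self) -> dict:
        return {
            "name": self.topology_name,
            "k": self.k,
            "n": self.n,
            "nll": float(self.nll),
            "aicc": float(self.aicc),
            "params": {k: float(v) for k, v in self.params.items()},
            "convergence": self.converged,
        }


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------


def profile_ci(
    fit: LineageFitResults,
    param: str,
    level: float = 0.95,
    step: float | None = None,
    max_steps: int = 60,
    max_nfev: int = 150,
) -> ProfileResult:
    """Profile-likelihood confidence interval for one parameter.

    Walks the parameter away from its estimate on a log10 grid
    (re-optimising all other parameters with warm starts) until the
    profiled NLL rises by the chi-square(1) threshold (1.92 for 95%),
    then interpolates the crossing.  A profile that hits the search
    bounds before crossing is flagged one-sided rather than failed.
    Parameter vectors inside the threshold are collected as band
    samples for prediction/flux uncertainty propagation.
    """
    if not fit.converged:
        raise ValueError("profile requires a converged fit")
    model = fit.model
    try:
        j = model.param_names.index(param)
    except ValueError:
        raise ValueError(f"unknown parameter {param!r}") from None
    from scipy.stats import chi2

    thresh = 0.5 * chi2.ppf(level, 1)
    lo, hi = model.bounds(fit.config)
    sigma = fit.sigma if fit.sigma is not None else model._sigma
    free = [i for i in range(len(model.param_names)) if i != j]

    def profiled_nll(val_log, warm):
        def res(sub):
            th = np.empty(len(model.param_names))
            th[free] = sub
            th[j] = val_log
            return model.residuals(th, sigma)

        sol = least_squares(res, warm, bounds=(lo[free], hi[free]), method="trf",
                            x_scale="jac", max_nfev=max_nfev,
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        const = float(np.sum(np.log(sigma))) if sigma is not None else 0.0
        return float(sol.cost) + const, sol.x

    base = fit.nll
    if step is None:
        # probe the local curvature so ~5 steps reach the threshold
        probe = 0.02
        nll_p, _ = profiled_nll(min(fit.theta[j] + probe, hi[j]), fit.theta[free].copy())
        rise = max(nll_p - base, 1e-4)
        est_cross = probe * np.sqrt(thresh / rise)
        step = float(np.clip(est_cross / 5.0, 0.005, 0.15))
    pts = [(fit.theta[j], base, fit.theta.copy())]
    flags = {}
    for direction in (-1.0, +1.0):
        warm = fit.theta[free].copy()
        val = fit.theta[j]
        hit_bound = True
        for _ in range(max_steps):
            val = val + direction * step
            if val < lo[j] or val > hi[j]:
                break
            nll_v, warm = profiled_nll(val, warm)
            th = np.empty(len(model.param_names))
            th[free] = warm
            th[j] = val
            pts.append((val, nll_v, th))
            if nll_v - base > thresh + 0.5:
                hit_bound = False
                break
        flags[direction] = hit_bound

    pts.sort(key=lambda x: x[0])
    vals = np.array([p[0] for p in pts])
    nlls = np.array([p[1] for p in pts])

    def crossing(side):
        jbest = int(np.argmin(np.abs(vals - fit.theta[j])))
        if side < 0:
            idx = range(jbest, -1, -1)
        else:
            idx = range(jbest, len(vals))
        prev_v, prev_d = fit.theta[j], 0.0
        for i in idx:
            d = nlls[i] - base
            if d > thresh:
                # linear interpolation in log10 between prev and this point
                w = (thresh - prev_d) / (d - prev_d)
                return prev_v + w * (vals[i] - prev_v)
            prev_v, prev_d = vals[i], d
        return lo[j] if side < 0 else hi[j]

    ci = (10.0 ** crossing(-1), 10.0 ** crossing(+1))
    band = np.array([p[2] for p in pts if p[1] - base <= thresh])
    grid = np.column_stack([10.0 ** vals, nlls])
    return ProfileResult(
        param=param,
        grid=grid,
        ci=ci,
        level=level,
        one_sided_lower=flags[-1.0],
        one_sided_upper=flags[+1.0],
        band_thetas=band,
    )


# ---------------------------------------------------------------------------
# spec-style functional surface
# ---------------------------------------------------------------------------


def negative_log_likelihood(pred, obs: ObservationTable, error_model: ErrorModel) -> float:
    """Gaussian NLL of an ObservablePrediction against an observation table.

    NLL = sum_i [ (y_i - yhat_i)^2 / (2 sigma_i^2) + ln sigma_i ]
    (additive constants dropped).  Observations without a matching
    prediction are excluded with a logged count.
    """
    df = obs.df
    n_missing = 0
    resid, sig = [], []
    for _, row in df.iterrows():
        try:
            series = pred.lookup(row.compartment, row.observable)
            ti = np.where(np.isclose(pred.t, row.time_days))[0]
            if len(ti) == 0:
                n_missing += 1
                continue
            yhat = series[ti[0]]
        except (ValueError, KeyError):
            n_missing += 1
            continue
        if not np.isfinite(yhat):
            n_missing += 1
            continue
        if error_model.mode == "use_reported_sem":
            s = row["sem"]
        else:
            s = error_model.sigma.get(row.observable)
            if s is not None and row.observable in error_model.relative_kinds:
                s = s * abs(row.value)
        if s is None or not np.isfinite(s) or s <= 0:
            raise ValueError(f"zero or missing sigma for row {row.to_dict()}")
        resid.append((row.value - yhat) / s)
        sig.append(s)
    if n_missing:
        log.info("negative_log_likelihood: %d observations had no prediction", n_missing)
    r = np.asarray(resid)
    return 0.5 * float(np.sum(r * r)) + float(np.sum(np.log(sig)))


def fit_model(
    topology: LineageTopology,
    obs: ObservationTable,
    config: FitConfig | None = None,
    error_model: ErrorModel | None = None,
    init: str = "steady_state",
) -> LineageFitResults:
    """Fit one topology by multistart maximum likelihood."""
    cfg = config or FitConfig()
    return LineageModel(topology, obs, error_model=error_model, init=init).fit(cfg)
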