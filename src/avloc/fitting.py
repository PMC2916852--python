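"""Per-subject maximum-likelihood fitting with simulation-based likelihoods.

The causal-inference observer has no closed-form response density once a
decision strategy is attached (selection and matching produce mixtures
whose weights depend on the trial's sensations), so the likelihood of a
subject's responses is built by Monte-Carlo simulation: for each stimulus
condition the model's predicted response distribution is estimated from a
large sample of simulated trials, binned on an azimuth grid, floored, and
renormalized; the data log-likelihood is the sum of log predicted
probabilities of the observed responses (bisensory trials contribute both
the auditory and the visual report).

Two numerical choices keep the optimization well behaved:

* **Common random numbers** — one fixed set of standard-normal and uniform
  draws per fit is reused at every parameter evaluation, so the likelihood
  surface is a deterministic function of the parameters and a bounded
  derivative-free optimizer (multi-start Powell) can be applied.
* **Probability floor** — every bin receives a small floor before
  renormalization so an observed response in an unvisited bin contributes
  a large-but-finite penalty rather than minus infinity.

Goodness of fit is summarized by the Nagelkerke generalized coefficient of
determination against a strategy-free null model (one Gaussian per
condition type and modality, fitted to the pooled responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from ._kernels import STRATEGY_CODES, bisensory_responses
from .datasets import SubjectDataset
from .model import STRATEGIES, ModelParams, estimate_c2

__all__ = [
    "FitConfig",
    "FitResult",
    "response_loglik",
    "fit_strategy",
    "fit_all_strategies",
    "null_loglik",
    "nagelkerke_r2",
]


@dataclass(frozen=True)
class FitConfig:
    """Settings for likelihood construction and optimization.

    ``mc_samples`` simulated trials per condition build each predicted
    histogram (bin width ``bin_width`` degrees over [grid_lo, grid_hi],
    floor ``prob_floor`` per bin before renormalization).  The optimizer
    runs ``restarts`` bounded Powell searches — the first from ``start``
    (typical-observer values), the rest from random draws over the
    bounds — each capped at ``max_evals`` likelihood evaluations, and
    polishes the best optimum with one further search.  ``seed`` fixes
    both the common random numbers and the restart draws.
    """

    mc_samples: int = 10_000
    bin_width: float = 1.0
    grid_lo: float = -67.0
    grid_hi: float = 67.0
    prob_floor: float = 1e-6
    restarts: int = 20
    max_evals: int = 400
    polish: bool = True
    seed: int = 0
    fit_criterion: bool = False
    bounds_sigma_A: tuple[float, float] = (0.1, 45.0)
    bounds_sigma_V: tuple[float, float] = (0.1, 45.0)
    bounds_sigma_P: tuple[float, float] = (1.0, 200.0)
    bounds_p_common: tuple[float, float] = (0.0, 1.0)
    bounds_criterion: tuple[float, float] = (0.0, 1.0)
    start: ModelParams = field(
        default_factory=lambda: ModelParams(
            sigma_A=8.0, sigma_V=2.0, sigma_P=30.0, p_common=0.5
        )
    )

    @property
    def n_bins(self) -> int:
        return int(round((self.grid_hi - self.grid_lo) / self.bin_width))

    @property
    def n_free_params(self) -> int:
        return 5 if self.fit_criterion else 4

    def bounds(self) -> list[tuple[float, float]]:
        b = [self.bounds_sigma_A, self.bounds_sigma_V, self.bounds_sigma_P, self.bounds_p_common]
        if self.fit_criterion:
            b.append(self.bounds_criterion)
        return b

    def pack(self, params: ModelParams) -> np.ndarray:
        theta = [params.sigma_A, params.sigma_V, params.sigma_P, params.p_common]
        if self.fit_criterion:
            theta.append(params.criterion)
        return np.array(theta)

    def unpack(self, theta: np.ndarray) -> ModelParams:
        criterion = float(theta[4]) if self.fit_criterion else 0.5
        return ModelParams(
            sigma_A=float(theta[0]),
            sigma_V=float(theta[1]),
            sigma_P=float(theta[2]),
            p_common=float(theta[3]),
            criterion=criterion,
        )


@dataclass
class FitResult:
    """Outcome of fitting one strategy to one subject."""

    strategy: str
    params: ModelParams
    loglik: float
    null_loglik: float
    r2: float
    n_responses: int
    n_free_params: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "strategy": self.strategy,
            "params": {
                "sigma_A": p.sigma_A,
                "sigma_V": p.sigma_V,
                "sigma_P": p.sigma_P,
                "p_common": p.p_common,
                "criterion": p.criterion,
            },
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "r2": self.r2,
            "n_responses": self.n_responses,
            "n_free_params": self.n_free_params,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            strategy=d["strategy"],
            params=ModelParams(**d["params"]),
            loglik=d["loglik"],
            null_loglik=d["null_loglik"],
            r2=d["r2"],
            n_responses=d["n_responses"],
            n_free_params=d["n_free_params"],
            diagnostics=d.get("diagnostics", {}),
        )


class MonteCarloLikelihood:
    """Deterministic simulated-response log-likelihood for one subject and strategy.

    Conditions are grouped (auditory-only, visual-only, bisensory) and the
    per-condition sensation noise, uniform matching draws, and observed
    response bin counts are precomputed once; each call to :meth:`loglik`
    then only re-runs the closed-form model arithmetic and a histogram.
    """

    def __init__(self, data: SubjectDataset, strategy: str, config: FitConfig):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        if config.mc_samples < 1000:
            raise ValueError("mc_samples must be at least 1000 for a usable likelihood")
        self.strategy = strategy
        self.config = config
        conds = data.conditions()
        # stable grouping: auditory-only, visual-only, bisensory
        self.conds_A = [c for c in conds if c.cond_type == "A"]
        self.conds_V = [c for c in conds if c.cond_type == "V"]
        self.conds_AV = [c for c in conds if c.cond_type == "AV"]
        self.n_cond = len(conds)
        rng = np.random.default_rng(config.seed)
        mc = config.mc_samples
        # common random numbers, fixed for the lifetime of the engine
        self._z_A_uni = rng.standard_normal((len(self.conds_A), mc))
        self._z_V_uni = rng.standard_normal((len(self.conds_V), mc))
        self._z_A_bi = rng.standard_normal((len(self.conds_AV), mc))
        self._z_V_bi = rng.standard_normal((len(self.conds_AV), mc))
        self._xi = rng.uniform(size=(len(self.conds_AV), mc))
        self._s_A_uni = np.array([c.s_A for c in self.conds_A])[:, None]
        self._s_V_uni = np.array([c.s_V for c in self.conds_V])[:, None]
        self._s_A_bi = np.array([c.s_A for c in self.conds_AV])[:, None]
        self._s_V_bi = np.array([c.s_V for c in self.conds_AV])[:, None]
        self._prepare_observed(data)

    # -- observed data ----------------------------------------------------
    def _bin_index(self, r: np.ndarray) -> np.ndarray:
        cfg = self.config
        idx = np.floor((np.asarray(r, dtype=float) - cfg.grid_lo) / cfg.bin_width)
        return np.clip(idx, 0, cfg.n_bins - 1).astype(np.intp)

    def _prepare_observed(self, data: SubjectDataset) -> None:
        cfg = self.config
        t = data.trials
        self.n_responses = data.n_responses
        n_clipped = 0

        def counts_for(conds, col):
            nonlocal n_clipped
            out = np.zeros((len(conds), cfg.n_bins))
            for i, c in enumerate(conds):
                mask = t["cond_type"] == c.cond_type
                if c.s_A is not None:
                    mask &= t["s_A"] == c.s_A
                if c.s_V is not None:
                    mask &= t["s_V"] == c.s_V
                r = t.loc[mask, col].to_numpy(dtype=float)
                n_clipped += int(((r < cfg.grid_lo) | (r >= cfg.grid_hi)).sum())
                out[i] = np.bincount(self._bin_index(r), minlength=cfg.n_bins)
            return out

        self._obs_A_uni = counts_for(self.conds_A, "resp_A")
        self._obs_V_uni = counts_for(self.conds_V, "resp_V")
        self._obs_A_bi = counts_for(self.conds_AV, "resp_A")
        self._obs_V_bi = counts_for(self.conds_AV, "resp_V")
        self.n_clipped = n_clipped
        if n_clipped:
            warnings.warn(
                f"{n_clipped} observed responses fell outside the response grid and were "
                "clipped to the edge bins",
                stacklevel=2,
            )

    # -- predicted distributions ------------------------------------------
    def _log_probs(self, r: np.ndarray) -> np.ndarray:
        """Row-wise binned log-probabilities with floor and renormalization."""
        cfg = self.config
        n_rows = r.shape[0]
        if n_rows == 0:
            return np.zeros((0, cfg.n_bins))
        idx = self._bin_index(r) + cfg.n_bins * np.arange(n_rows)[:, None]
        counts = np.bincount(idx.ravel(), minlength=n_rows * cfg.n_bins).reshape(n_rows, cfg.n_bins)
        p = counts / cfg.mc_samples + cfg.prob_floor
        p /= p.sum(axis=1, keepdims=True)
        return np.log(p)

    def predicted_responses(self, params: ModelParams) -> dict[str, np.ndarray]:
        """Simulated final reports per condition group under the engine's fixed draws."""
        r_A_uni = estimate_c2(self._s_A_uni + params.sigma_A * self._z_A_uni, params.sigma_A, params)
        r_V_uni = estimate_c2(self._s_V_uni + params.sigma_V * self._z_V_uni, params.sigma_V, params)
        out = {"A_uni": r_A_uni, "V_uni": r_V_uni}
        if self.conds_AV:
            out["A_bi"], out["V_bi"] = bisensory_responses(
                self._s_A_bi[:, 0],
                self._s_V_bi[:, 0],
                self._z_A_bi,
                self._z_V_bi,
                self._xi,
                params.sigma_A,
                params.sigma_V,
                params.sigma_P,
                params.p_common,
                params.criterion,
                STRATEGY_CODES[self.strategy],
            )
        else:
            out["A_bi"] = out["V_bi"] = np.zeros((0, self.config.mc_samples))
        return out

    def loglik(self, params: ModelParams) -> float:
        """Log-likelihood of the subject's responses; deterministic given the config seed."""
        pred = self.predicted_responses(params)
        total = 0.0
        for key, obs in (
            ("A_uni", self._obs_A_uni),
            ("V_uni", self._obs_V_uni),
            ("A_bi", self._obs_A_bi),
            ("V_bi", self._obs_V_bi),
        ):
            if obs.shape[0]:
                total += float(np.sum(obs * self._log_probs(pred[key])))
        return total

    def loglik_theta(self, theta: np.ndarray) -> float:
        # Powell's line search may overshoot the box by rounding error
        lo, hi = np.transpose(self.config.bounds())
        return self.loglik(self.config.unpack(np.clip(theta, lo, hi)))


def response_loglik(
    data: SubjectDataset,
    params: ModelParams,
    strategy: str,
    mc_samples: int = 10_000,
    seed: int = 0,
    config: Optional[FitConfig] = None,
) -> float:
    """Simulated-response log-likelihood of ``params`` for one subject and strategy."""
    if config is None:
        config = FitConfig(mc_samples=mc_samples, seed=seed)
    else:
        config = replace(config, mc_samples=mc_samples, seed=seed)
    return MonteCarloLikelihood(data, strategy, config).loglik(params)


def _random_start(rng: np.random.Generator, config: FitConfig) -> np.ndarray:
    """Random restart point: log-uniform over sigma bounds, uniform over probabilities."""
    theta = []
    for lo, hi in (config.bounds_sigma_A, config.bounds_sigma_V, config.bounds_sigma_P):
        theta.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    theta.append(rng.uniform(*config.bounds_p_common))
    if config.fit_criterion:
        theta.append(rng.uniform(*config.bounds_criterion))
    return np.array(theta)


def fit_strategy(data: SubjectDataset, strategy: str, config: Optional[FitConfig] = None) -> FitResult:
    """Maximum-likelihood fit of one strategy to one subject.

    Multi-start bounded Powell search on the common-random-numbers likelihood
    surface; the best restart is optionally polished by a second search
    from its optimum.  The returned result carries the null-model
    log-likelihood and Nagelkerke R^2, plus per-restart diagnostics.
    """
    if config is None:
        config = FitConfig()
    engine = MonteCarloLikelihood(data, strategy, config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    starts = [config.pack(config.start)]
    starts += [_random_start(rng, config) for _ in range(max(config.restarts - 1, 0))]
    bounds = config.bounds()
    # Powell's bracketing line searches step across the staircase-like
    # plateaus the hard selection/matching rules carve into the common-
    # random-numbers likelihood surface; simplex methods stall on them
    options = {"maxfev": config.max_evals, "xtol": 1e-3, "ftol": 1e-3}

    best = None
    traces = []
    for x0 in starts:
        res = minimize(
            lambda th: -engine.loglik_theta(th),
            x0,
            method="Powell",
            bounds=bounds,
            options=options,
        )
        traces.append({"x0": list(map(float, x0)), "fun": float(res.fun), "nfev": int(res.nfev), "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {len(starts)} restarts failed; traces: {traces}")
    if config.polish:
        res = minimize(
            lambda th: -engine.loglik_theta(th),
            best.x,
            method="Powell",
            bounds=bounds,
            options={"maxfev": 2 * config.max_evals, "xtol": 1e-4, "ftol": 1e-4},
        )
        if res.fun < best.fun:
            best = res
    params = config.unpack(best.x)
    ll = float(-best.fun)
    l0 = null_loglik(data, config)
    return FitResult(
        strategy=strategy,
        params=params,
        loglik=ll,
        null_loglik=l0,
        r2=nagelkerke_r2(ll, l0, engine.n_responses),
        n_responses=engine.n_responses,
        n_free_params=config.n_free_params,
        diagnostics={
            "restarts": len(starts),
            "n_converged": sum(t["converged"] for t in traces),
            "n_clipped_responses": engine.n_clipped,
            "seed": config.seed,
            "mc_samples": config.mc_samples,
            "traces": traces,
        },
    )


def fit_all_strategies(
    data: SubjectDataset,
    config: Optional[FitConfig] = None,
    strategies: Sequence[str] = STRATEGIES,
) -> dict[str, FitResult]:
    """Fit each candidate strategy with the same config (and hence the same noise draws)."""
    return {s: fit_strategy(data, s, config) for s in strategies}


def null_loglik(data: SubjectDataset, config: Optional[FitConfig] = None) -> float:
    """Strategy-free null model: one Gaussian per condition type and modality.

    Responses are pooled across conditions of the same type (A, V, AV) and
    modality, a Gaussian is fitted by moments, discretized on the same bin
    grid with the same floor, and the pooled log-likelihood summed.  This
    deliberately ignores stimulus locations, so it captures only the
    overall spread of reports.
    """
    if config is None:
        config = FitConfig()
    edges = config.grid_lo + config.bin_width * np.arange(config.n_bins + 1)
    t = data.trials
    total = 0.0
    for cond_type, col in (("A", "resp_A"), ("V", "resp_V"), ("AV", "resp_A"), ("AV", "resp_V")):
        r = t.loc[t["cond_type"] == cond_type, col].dropna().to_numpy(dtype=float)
        if r.size == 0:
            continue
        mu, sd = float(r.mean()), max(float(r.std()), 0.5)
        cdf = norm.cdf(edges, loc=mu, scale=sd)
        p = np.diff(cdf) + config.prob_floor
        p /= p.sum()
        idx = np.clip(np.floor((r - config.grid_lo) / config.bin_width), 0, config.n_bins - 1).astype(np.intp)
        total += float(np.log(p[idx]).sum())
    return total


def nagelkerke_r2(loglik: float, null_loglik: float, n: int) -> float:
    """Nagelkerke generalized coefficient of determination.

    R^2 = [1 - exp(-(2/n)(L1 - L0))] / [1 - exp((2/n) L0)], where L1 and
    L0 are the model and null log-likelihoods over n responses.  Equals 0
    when the model does no better than the null and approaches 1 as the
    discrete response model approaches perfect prediction; negative values
    (model worse than null) are allowed and signal a failed fit.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    cox_snell = 1.0 - np.exp(-(2.0 / n) * (loglik - null_loglik))
    max_r2 = 1.0 - np.exp((2.0 / n) * null_loglik)
    return float(cox_snell / max_r2)
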