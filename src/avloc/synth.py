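"""Synthetic observers under the standard audiovisual localization design.

The standard session crosses 5 speaker azimuths (-13, -6.5, 0, 6.5, 13 deg)
into 5 auditory-only, 5 visual-only, and 25 bisensory conditions, each
repeated 15 times in pseudorandom order — 525 test trials per subject.
Subjects are simulated trial by trial from the causal-inference model with
a known generating strategy and parameter set, so the fitting and
classification pipeline can be validated by parameter and strategy
recovery.  Between-subject heterogeneity is emulated by jittering the
typical-observer parameters (log-normal for the sigmas, logistic-normal
for p_common).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datasets import COLUMNS, SubjectDataset
from .model import (
    MEAN_SUBJECT_PARAMS,
    STRATEGIES,
    ModelParams,
    apply_strategy,
    estimate_c2,
    structure_estimates,
)
from .simulate import SPEAKER_AZIMUTHS, DEFAULT_GRID, StimulusCondition, quantize_responses

__all__ = [
    "ExperimentDesign",
    "SyntheticSubjectSpec",
    "build_design",
    "generate_subject",
    "generate_cohort",
    "default_param_sampler",
    "fixed_param_sampler",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """A trial sequence over the standard condition set.

    ``order`` maps each trial to an index into ``conditions``; the
    pseudorandom interleaving is reproducible from ``seed``.
    """

    conditions: tuple[StimulusCondition, ...]
    repetitions: int
    order: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.order)

    def trial_conditions(self) -> list[StimulusCondition]:
        return [self.conditions[i] for i in self.order]


def standard_conditions(azimuths: Sequence[float] = SPEAKER_AZIMUTHS) -> tuple[StimulusCondition, ...]:
    """5 auditory-only + 5 visual-only + the full 5x5 bisensory cross (35 conditions)."""
    conds = [StimulusCondition(s_A=a) for a in azimuths]
    conds += [StimulusCondition(s_V=v) for v in azimuths]
    conds += [StimulusCondition(s_A=a, s_V=v) for a in azimuths for v in azimuths]
    return tuple(conds)


def build_design(repetitions: int = 15, seed: int = 0) -> ExperimentDesign:
    """Standard design with each condition repeated ``repetitions`` times in shuffled order."""
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    conditions = standard_conditions()
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(len(conditions)), repetitions))
    return ExperimentDesign(conditions=conditions, repetitions=repetitions, order=order, seed=seed)


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Provenance record for one synthetic subject: who generated the data and how."""

    subject: str
    strategy: str
    params: ModelParams
    seed: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")


def generate_subject(spec: SyntheticSubjectSpec, design: ExperimentDesign) -> SubjectDataset:
    """Simulate one subject's full session trial by trial.

    Each trial draws fresh sensations (and a fresh uniform xi for the
    matching strategy), applies the generating strategy, and reports the
    resulting estimate quantized to the 0.1-deg cursor resolution and
    clipped to the screen.  Unisensory trials use single-cue shrinkage.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    n = design.n_trials
    s_A = np.array([c.s_A if c.s_A is not None else np.nan for c in design.trial_conditions()])
    s_V = np.array([c.s_V if c.s_V is not None else np.nan for c in design.trial_conditions()])
    has_A, has_V = ~np.isnan(s_A), ~np.isnan(s_V)

    # one noise draw per trial and channel; draws for absent channels are discarded
    x_A = s_A + p.sigma_A * rng.standard_normal(n)
    x_V = s_V + p.sigma_V * rng.standard_normal(n)
    xi = rng.uniform(size=n)

    resp_A = np.full(n, np.nan)
    resp_V = np.full(n, np.nan)
    both = has_A & has_V
    if both.any():
        est = structure_estimates(x_A[both], x_V[both], p)
        r_A, r_V = apply_strategy(spec.strategy, est, p, xi=xi[both])
        resp_A[both] = r_A
        resp_V[both] = r_V
    only_A, only_V = has_A & ~has_V, has_V & ~has_A
    resp_A[only_A] = estimate_c2(x_A[only_A], p.sigma_A, p)
    resp_V[only_V] = estimate_c2(x_V[only_V], p.sigma_V, p)
    resp_A[has_A] = quantize_responses(resp_A[has_A], DEFAULT_GRID)
    resp_V[has_V] = quantize_responses(resp_V[has_V], DEFAULT_GRID)

    cond_type = np.where(both, "AV", np.where(has_A, "A", "V"))
    trials = pd.DataFrame(
        {
            "subject": spec.subject,
            "trial": np.arange(n),
            "cond_type": cond_type,
            "s_A": s_A,
            "s_V": s_V,
            "resp_A": resp_A,
            "resp_V": resp_V,
        }
    )[COLUMNS]
    meta = {
        "subject": spec.subject,
        "strategy": spec.strategy,
        "sigma_A": f"{p.sigma_A:.6g}",
        "sigma_V": f"{p.sigma_V:.6g}",
        "sigma_P": f"{p.sigma_P:.6g}",
        "p_common": f"{p.p_common:.6g}",
        "criterion": f"{p.criterion:.6g}",
        "subject_seed": str(spec.seed),
        "design_seed": str(design.seed),
        "repetitions": str(design.repetitions),
    }
    return SubjectDataset(subject=spec.subject, trials=trials, meta=meta)


def default_param_sampler(
    rng: np.random.Generator,
    center: ModelParams = MEAN_SUBJECT_PARAMS,
    geometric_sd: float = 1.25,
    logit_sd: float = 0.5,
) -> ModelParams:
    """Between-subject parameter heterogeneity around the typical observer.

    The three sigmas get independent log-normal jitter with geometric SD
    ``geometric_sd`` (positive support, ~25% spread); p_common is jittered
    on the logit scale with SD ``logit_sd`` so it stays inside (0, 1).
    """
    log_sd = np.log(geometric_sd)
    logit = np.log(center.p_common / (1.0 - center.p_common)) + logit_sd * rng.standard_normal()
    return ModelParams(
        sigma_A=center.sigma_A * np.exp(log_sd * rng.standard_normal()),
        sigma_V=center.sigma_V * np.exp(log_sd * rng.standard_normal()),
        sigma_P=center.sigma_P * np.exp(log_sd * rng.standard_normal()),
        p_common=float(1.0 / (1.0 + np.exp(-logit))),
        criterion=center.criterion,
    )


def fixed_param_sampler(params: ModelParams = MEAN_SUBJECT_PARAMS) -> Callable[[np.random.Generator], ModelParams]:
    """Sampler that returns the same parameter set for every subject."""
    return lambda rng: params


def generate_cohort(
    n_per_strategy: Union[int, Mapping[str, int]],
    param_sampler: Optional[Callable[[np.random.Generator], ModelParams]] = None,
    seed: int = 0,
    repetitions: int = 15,
    strategies: Sequence[str] = STRATEGIES,
) -> tuple[list[SubjectDataset], dict]:
    """Generate a cohort of synthetic subjects with full provenance.

    ``n_per_strategy`` is either one count applied to every strategy or a
    mapping strategy -> count (zero allowed).  Each subject gets its own
    design shuffle, parameter draw, and response seed, all derived from
    ``seed``.  Returns the datasets and a provenance dictionary recording
    every spec.
    """
    if param_sampler is None:
        param_sampler = default_param_sampler
    if isinstance(n_per_strategy, int):
        counts = {s: n_per_strategy for s in strategies}
    else:
        counts = {s: int(n_per_strategy.get(s, 0)) for s in strategies}
    rng = np.random.default_rng(seed)
    datasets: list[SubjectDataset] = []
    provenance: dict = {"seed": seed, "repetitions": repetitions, "subjects": []}
    idx = 0
    for strategy in strategies:
        for _ in range(counts[strategy]):
            params = param_sampler(rng)
            subject_seed = int(rng.integers(2**31 - 1))
            design_seed = int(rng.integers(2**31 - 1))
            spec = SyntheticSubjectSpec(
                subject=f"s{idx:03d}", strategy=strategy, params=params, seed=subject_seed
            )
            design = build_design(repetitions=repetitions, seed=design_seed)
            datasets.append(generate_subject(spec, design))
            provenance["subjects"].append(
                {
                    "subject": spec.subject,
                    "strategy": strategy,
                    "params": {
                        "sigma_A": params.sigma_A,
                        "sigma_V": params.sigma_V,
                        "sigma_P": params.sigma_P,
                        "p_common": params.p_common,
                        "criterion": params.criterion,
                    },
                    "subject_seed": subject_seed,
                    "design_seed": design_seed,
                }
            )
            idx += 1
    return datasets, provenance
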