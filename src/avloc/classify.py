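"""Strategy classification per subject and cohort-level tabulation.

Each subject is classified by the decision strategy whose maximum-likelihood
fit attains the highest log-likelihood.  Confidence is expressed by the
log-likelihood margin — best minus second-best, in natural-log units — and
subjects are included in the headline tabulation only when the margin
exceeds a threshold (3 by default, the conventional cut for substantial
evidence; 10 as a sensitivity check for decisive evidence).  When the
biased-selection variant with a free criterion competes, the extra
parameter is penalized via the Bayesian information criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult

__all__ = [
    "ClassificationResult",
    "CohortSummary",
    "classify_subject",
    "bic",
    "tabulate_cohort",
]

DEFAULT_MARGIN_THRESHOLDS = (3.0, 10.0)


@dataclass
class ClassificationResult:
    """One subject's classification outcome across candidate strategies."""

    subject: str
    logliks: dict[str, float]
    winner: str
    margin: float
    tie: bool
    included: dict[float, bool]
    bic: Optional[dict[str, float]] = None

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "logliks": self.logliks,
            "winner": self.winner,
            "margin": self.margin,
            "tie": self.tie,
            "included": {str(k): v for k, v in self.included.items()},
            "bic": self.bic,
        }


def bic(fit: FitResult, n_responses: Optional[int] = None) -> float:
    """Bayesian information criterion, k*ln(n) - 2*loglik (lower is better).

    k is the fit's free-parameter count (4 for the standard models, 5 for
    biased selection) and n the number of responses entering the
    likelihood; defaults to the count stored on the fit.
    """
    n = fit.n_responses if n_responses is None else n_responses
    if n < 1:
        raise ValueError("n_responses must be at least 1")
    return float(fit.n_free_params * np.log(n) - 2.0 * fit.loglik)


def classify_subject(
    fits: Mapping[str, FitResult],
    margin_threshold: float = 3.0,
    thresholds: Sequence[float] = DEFAULT_MARGIN_THRESHOLDS,
    subject: str = "",
    with_bic: bool = False,
) -> ClassificationResult:
    """Pick the winning strategy for one subject by maximum likelihood.

    The winner is the strategy with the highest log-likelihood; the margin
    is its lead over the runner-up.  A subject is included under a
    threshold iff margin > threshold (strictly); exact ties exclude the
    subject under every threshold and set the tie flag.  ``margin_threshold``
    is folded into ``thresholds`` so the caller's primary criterion is
    always reported.
    """
    if len(fits) < 2:
        raise ValueError("classification needs at least two strategy fits")
    items = sorted(fits.items(), key=lambda kv: kv[1].loglik, reverse=True)
    winner, best = items[0]
    margin = float(best.loglik - items[1][1].loglik)
    tie = margin == 0.0
    all_thresholds = sorted(set(thresholds) | {margin_threshold})
    included = {th: (not tie) and margin > th for th in all_thresholds}
    bics = {s: bic(f) for s, f in fits.items()} if with_bic else None
    return ClassificationResult(
        subject=subject or getattr(best, "subject", ""),
        logliks={s: float(f.loglik) for s, f in fits.items()},
        winner=winner,
        margin=margin,
        tie=tie,
        included=included,
        bic=bics,
    )


@dataclass
class CohortSummary:
    """Counts and percentages per strategy under each inclusion regime."""

    table: pd.DataFrame
    margin_stats: dict[float, dict[str, float]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def tabulate_cohort(
    results: Sequence[ClassificationResult],
    thresholds: Sequence[float] = DEFAULT_MARGIN_THRESHOLDS,
) -> CohortSummary:
    """Cohort-level strategy tabulation with margin-threshold sensitivity.

    One row per strategy; the no-exclusion totals plus, for each margin
    threshold, the counts and percentages among included subjects.  Margin
    means and medians among included subjects are reported per threshold.
    Percentages are computed over the included subjects of each regime.
    """
    if not results:
        raise ValueError("no classification results to tabulate")
    strategies = sorted({r.winner for r in results} | set(results[0].logliks))
    rows = []
    for s in strategies:
        row: dict = {"strategy": s}
        wins = [r for r in results if r.winner == s and not r.tie]
        row["count_all"] = len([r for r in results if r.winner == s])
        row["pct_all"] = 100.0 * row["count_all"] / len(results)
        for th in thresholds:
            inc = [r for r in wins if r.included.get(th, r.margin > th)]
            n_inc_total = sum(1 for r in results if (not r.tie) and r.margin > th)
            row[f"count_m{th:g}"] = len(inc)
            row[f"pct_m{th:g}"] = 100.0 * len(inc) / n_inc_total if n_inc_total else 0.0
        rows.append(row)
    margin_stats = {}
    for th in thresholds:
        margins = [r.margin for r in results if (not r.tie) and r.margin > th]
        margin_stats[th] = {
            "n_included": len(margins),
            "margin_mean": float(np.mean(margins)) if margins else float("nan"),
            "margin_median": float(np.median(margins)) if margins else float("nan"),
        }
    return CohortSummary(table=pd.DataFrame(rows), margin_stats=margin_stats)
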