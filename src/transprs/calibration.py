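"""Cross-population PRS distribution comparison and percentile remapping.

The same PRS can have markedly different means across ancestry groups even
when effect sizes transfer, so a percentile computed against the wrong
reference distribution misstates risk.  This module summarizes per-group
control distributions, maps percentiles between populations under a normal
model (with an empirical companion for non-normal scores), and quantifies
the risk miscalibration incurred by using another population's
distribution as reference.

Percentile maps use *control* distributions only: cases are risk-enriched
and would bias the population reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import CohortTable
from .scoring import PRSVector


@dataclass
class PopulationStats:
    """Control-score summary for one ancestry group."""

    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DataError("control SD must be positive")
        if self.n < 2:
            raise DataError("need at least 2 controls")


def group_stats(prs: PRSVector, cohort: CohortTable):
    """Per-ancestry control means/SDs plus pairwise mean-difference tests.

    Returns ``(stats_list, tests)`` where ``tests`` is a DataFrame of
    two-sample unequal-variance (Welch) comparisons of control means for
    every group pair (empty with a single group).
    """
    df = cohort.df
    ctrl = df[cohort.control_mask]
    out: list[PopulationStats] = []
    samples: dict[str, np.ndarray] = {}
    for group, grp in ctrl.groupby("ancestry_group", sort=False):
        x = prs.scores.loc[grp["sample_id"]].to_numpy(float)
        if len(x) < 2:
            raise DataError(f"ancestry group {group!r} has fewer than 2 controls")
        out.append(
            PopulationStats(group=str(group), mean=float(x.mean()),
                            sd=float(x.std(ddof=1)), n=len(x))
        )
        samples[str(group)] = x
    rows = []
    for a, b in combinations(samples, 2):
        t, p = stats.ttest_ind(samples[a], samples[b], equal_var=False)
        rows.append((a, b, samples[a].mean() - samples[b].mean(), float(t), float(p)))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "pval"])
    return out, tests


def normal_percentile_map(
    source: PopulationStats, target: PopulationStats, pct: float
) -> float:
    """Map a percentile from the source to the target control distribution.

    The score at the source's ``pct`` quantile is re-ranked in the target:
    ``Phi((mu_s + sigma_s Phi^-1(pct) - mu_t) / sigma_t)``.  A strictly
    increasing bijection of (0, 1); composing with the reverse map is the
    identity.
    """
    if not (0 < pct < 1):
        raise DataError("percentile must lie in (0, 1)")
    x = source.mean + source.sd * stats.norm.ppf(pct)
    out = float(stats.norm.cdf((x - target.mean) / target.sd))
    # keep the output in the open interval even when Phi saturates
    tiny = np.finfo(float).tiny
    return min(max(out, tiny), 1.0 - np.finfo(float).epsneg)


def empirical_percentile_map(source_scores, target_scores, pct: float) -> float:
    """Distribution-free companion of :func:`normal_percentile_map`.

    The source ``pct`` quantile (linear interpolation) is located in the
    target sample's interpolated ECDF.  Converges to the normal map for
    Gaussian samples as both sizes grow.
    """
    if not (0 < pct < 1):
        raise DataError("percentile must lie in (0, 1)")
    src = np.sort(np.asarray(source_scores, dtype=float))
    tgt = np.sort(np.asarray(target_scores, dtype=float))
    if len(src) < 2 or len(tgt) < 2:
        raise DataError("need at least 2 scores on each side")
    x = np.quantile(src, pct)
    # interpolated ECDF: plotting positions (i - 0.5) / n
    pp = (np.arange(1, len(tgt) + 1) - 0.5) / len(tgt)
    return float(np.clip(np.interp(x, tgt, pp), 0.0, 1.0))


@dataclass
class CalibrationGap:
    """Risk consequences of scoring one population against another's
    distribution."""

    percentile: float
    mapped_percentile: float
    own_risk: float
    reference_risk: float

    @property
    def gap(self) -> float:
        """Reference-assigned minus own-calibrated risk (negative =
        underestimation)."""
        return self.reference_risk - self.own_risk


def risk_at_percentile(
    pop: PopulationStats,
    reference: PopulationStats,
    pct: float,
    risk_model,
) -> CalibrationGap:
    """Own-calibrated vs reference-calibrated risk for one individual.

    A woman at percentile ``pct`` of her own population's distribution is
    assigned percentile ``normal_percentile_map(pop, reference, pct)`` when
    the reference distribution is used instead.  ``risk_model`` maps a
    percentile to absolute risk (see
    :func:`transprs.absolute_risk.lifetime_risk_by_percentile`).  When the
    population mean is below the reference mean the mapped percentile -- and
    hence the communicated risk -- is systematically too low.
    """
    mapped = normal_percentile_map(pop, reference, pct)
    return CalibrationGap(
        percentile=pct,
        mapped_percentile=mapped,
        own_risk=float(risk_model(pct)),
        reference_risk=float(risk_model(mapped)),
    )
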