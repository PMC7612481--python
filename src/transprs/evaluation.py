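"""Association and discrimination metrics for PRSs.

Odds ratio per SD from covariate-adjusted logistic regression, hazard ratio
per SD from Cox proportional hazards, AUC by the Mann-Whitney rank statistic
with DeLong confidence intervals, fixed-effect (inverse-variance)
meta-analysis with Cochran's Q heterogeneity, plus two analytic checks
based on the equal-variance binormal score model:

* ``binormal_auc``: when case and control scores are normal with unit
  variance and mean gap ``ln(OR)``, AUC = Phi(ln(OR) / sqrt(2)).
* ``percentile_or_theoretical``: under a polygenic model in which the log
  odds is linear in a standard-normal score, the odds ratio comparing two
  percentile bands is a ratio of truncated-normal expectations of
  ``exp(beta z)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, NumericalError
from .io_formats import CohortTable, GenotypeMatrix
from .scoring import PRSVector

logger = logging.getLogger(__name__)


@dataclass
class EffectEstimate:
    """One study's effect size (OR or HR per SD) with its discrimination."""

    estimate: float
    ci_low: float
    ci_high: float
    log_se: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    label: str = ""
    n_case: int | None = None
    n_control: int | None = None
    n_events: int | None = None
    auc_se: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise DataError("confidence interval must bracket the estimate")
        if self.auc is not None and not (0 <= self.auc <= 1):
            raise DataError("AUC must lie in [0, 1]")


# ---------------------------------------------------------------------------
# AUC: rank statistic + DeLong variance
# ---------------------------------------------------------------------------

def auc_rank(case_scores, control_scores) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties half-credit."""
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if len(case) == 0 or len(ctrl) == 0:
        raise DataError("need both cases and controls for AUC")
    ranks = stats.rankdata(np.r_[case, ctrl])
    n1 = len(case)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * len(ctrl)))


def _placements(x: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """For each x: fraction of ref strictly below + half the ties."""
    lo = np.searchsorted(ref_sorted, x, side="left")
    hi = np.searchsorted(ref_sorted, x, side="right")
    return (lo + 0.5 * (hi - lo)) / len(ref_sorted)


def delong_auc_ci(case_scores, control_scores, alpha: float = 0.05):
    """AUC with DeLong variance CI.  Returns ``(auc, (lo, hi), se)``."""
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    v10 = _placements(case, np.sort(ctrl))       # per-case placements
    v01 = 1.0 - _placements(ctrl, np.sort(case))  # per-control placements
    auc = float(v10.mean())
    var = 0.0
    if len(case) > 1:
        var += v10.var(ddof=1) / len(case)
    if len(ctrl) > 1:
        var += v01.var(ddof=1) / len(ctrl)
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - zq * se), min(1.0, auc + zq * se)
    return auc, (lo, hi), se


# ---------------------------------------------------------------------------
# Association models
# ---------------------------------------------------------------------------

def fit_or_per_sd(
    prs: PRSVector,
    cohort: CohortTable,
    n_pcs: int = 10,
    adjust_stratum: bool = True,
    alpha: float = 0.05,
) -> EffectEstimate:
    """OR per SD from logistic regression, adjusted for PCs and stratum.

    The PRS should already be standardized to unit control SD.  The AUC is
    computed from the score alone (unadjusted), with a DeLong CI.
    """
    if cohort.mode != "binary":
        raise DataError("fit_or_per_sd requires a case/control cohort")
    df = cohort.df
    z = prs.scores.loc[df["sample_id"]].to_numpy()
    y = df["case"].to_numpy()
    design = [z.reshape(-1, 1)]
    pcs = cohort.pc_columns(n_pcs)
    if pcs:
        design.append(df[pcs].to_numpy(float))
    if adjust_stratum:
        dummies = pd.get_dummies(df["stratum"], drop_first=True, dtype=float)
        if dummies.shape[1]:
            design.append(dummies.to_numpy())
    M = sm.add_constant(np.column_stack(design))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, M).fit(disp=0)
    b, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(b) or not np.isfinite(se):
        raise NumericalError("logistic fit failed")
    zq = stats.norm.ppf(1 - alpha / 2)
    auc, auc_ci, auc_se = delong_auc_ci(z[y == 1], z[y == 0], alpha)
    return EffectEstimate(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - zq * se)),
        ci_high=float(np.exp(b + zq * se)),
        log_se=se,
        auc=auc,
        auc_ci=auc_ci,
        auc_se=auc_se,
        label=prs.label,
        n_case=int(y.sum()),
        n_control=int((1 - y).sum()),
    )


def fit_hr_per_sd(
    prs: PRSVector,
    cohort: CohortTable,
    n_pcs: int = 2,
    alpha: float = 0.05,
) -> EffectEstimate:
    """HR per SD from a Cox proportional-hazards partial-likelihood fit.

    Adjusted for the first ``n_pcs`` principal components present in the
    cohort table.  The AUC contrasts incident cases with censored subjects
    on the score alone.
    """
    from lifelines import CoxPHFitter

    if cohort.mode != "survival":
        raise DataError("fit_hr_per_sd requires a time-to-event cohort")
    df = cohort.df
    z = prs.scores.loc[df["sample_id"]].to_numpy()
    cols = {"time": df["time"].to_numpy(float), "event": df["event"].to_numpy(int), "prs": z}
    for c in cohort.pc_columns(n_pcs):
        cols[c] = df[c].to_numpy(float)
    frame = pd.DataFrame(cols)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    b = float(cph.params_["prs"])
    se = float(cph.standard_errors_["prs"])
    zq = stats.norm.ppf(1 - alpha / 2)
    ev = frame["event"].to_numpy() == 1
    auc, auc_ci, auc_se = delong_auc_ci(z[ev], z[~ev], alpha)
    return EffectEstimate(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - zq * se)),
        ci_high=float(np.exp(b + zq * se)),
        log_se=se,
        auc=auc,
        auc_ci=auc_ci,
        auc_se=auc_se,
        label=prs.label,
        n_events=int(ev.sum()),
        n_control=int((~ev).sum()),
    )


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    pooled: EffectEstimate
    q: float
    p_het: float
    k: int


def meta_fixed(estimates: list[EffectEstimate], alpha: float = 0.05) -> MetaResult:
    """Fixed-effect inverse-variance pooling on the log scale.

    Cochran's Q with k-1 degrees of freedom tests between-study
    heterogeneity.  AUCs are pooled the same way (on the AUC scale) when
    every study carries a DeLong standard error.
    """
    if not estimates:
        raise DataError("no estimates to pool")
    logs = np.array([np.log(e.estimate) for e in estimates])
    ses = np.array([e.log_se for e in estimates])
    if (ses <= 0).any():
        raise DataError("non-positive standard error in meta-analysis input")
    w = 1.0 / ses**2
    pooled_log = float((w * logs).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    q = float((w * (logs - pooled_log) ** 2).sum())
    k = len(estimates)
    p_het = float(stats.chi2.sf(q, k - 1)) if k > 1 else float("nan")
    zq = stats.norm.ppf(1 - alpha / 2)

    auc = auc_ci = auc_se = None
    if all(e.auc is not None and e.auc_se not in (None, 0) for e in estimates):
        wa = np.array([1.0 / e.auc_se**2 for e in estimates])
        aucs = np.array([e.auc for e in estimates])
        auc = float((wa * aucs).sum() / wa.sum())
        auc_se = float(1.0 / np.sqrt(wa.sum()))
        auc_ci = (max(0.0, auc - zq * auc_se), min(1.0, auc + zq * auc_se))

    pooled = EffectEstimate(
        estimate=float(np.exp(pooled_log)),
        ci_low=float(np.exp(pooled_log - zq * pooled_se)),
        ci_high=float(np.exp(pooled_log + zq * pooled_se)),
        log_se=pooled_se,
        auc=auc,
        auc_ci=auc_ci,
        auc_se=auc_se,
        label="meta",
        n_events=sum(e.n_events or 0 for e in estimates) or None,
    )
    return MetaResult(pooled=pooled, q=q, p_het=p_het, k=k)


# ---------------------------------------------------------------------------
# Binormal / polygenic-model checks
# ---------------------------------------------------------------------------

def binormal_auc(or_per_sd: float) -> float:
    """AUC implied by an OR per SD under the equal-variance binormal model."""
    return float(stats.norm.cdf(np.log(or_per_sd) / np.sqrt(2.0)))


def _tilted_band_mean(beta: float, lo: float, hi: float) -> float:
    """E[exp(beta Z) | Z in percentile band (lo, hi)], Z ~ N(0,1).

    Closed form via the truncated-normal mgf:
    ``exp(beta^2/2) (Phi(b - beta) - Phi(a - beta)) / (Phi(b) - Phi(a))``
    with ``a = Phi^-1(lo)``, ``b = Phi^-1(hi)``.
    """
    if not (0 <= lo < hi <= 1):
        raise DataError("percentile band must satisfy 0 <= lo < hi <= 1")
    a = stats.norm.ppf(lo) if lo > 0 else -np.inf
    b = stats.norm.ppf(hi) if hi < 1 else np.inf
    num = stats.norm.cdf(b - beta) - stats.norm.cdf(a - beta)
    den = hi - lo
    return float(np.exp(beta**2 / 2) * num / den)


def percentile_or_theoretical(
    or_per_sd: float,
    target_band: tuple[float, float],
    reference_band: tuple[float, float],
) -> float:
    """OR comparing two PRS percentile bands under the linear-log-OR model.

    ``OR = E[e^{beta Z} | Z in target] / E[e^{beta Z} | Z in reference]``
    with ``beta = ln(OR per SD)`` and ``Z ~ N(0, 1)``.
    """
    beta = np.log(or_per_sd)
    return _tilted_band_mean(beta, *target_band) / _tilted_band_mean(beta, *reference_band)


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def compute_pcs(gm: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Ancestry PCs from the standardized-genotype eigendecomposition.

    Columns are orthonormal left singular vectors of the centered, scaled
    dosage matrix, returned as covariate columns ``pc1..pck`` indexed by
    sample id.  ``k=0`` returns an empty frame.
    """
    if k < 0:
        raise DataError("k must be non-negative")
    idx = pd.Index(gm.sample_ids, name="sample_id")
    if k == 0:
        return pd.DataFrame(index=idx)
    X = gm.dosages.copy()
    mean = np.nanmean(X, axis=0)
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(mean, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    k = min(k, min(X.shape) - 1) if min(X.shape) > 1 else 1
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return pd.DataFrame(U[:, :k], index=idx, columns=[f"pc{i + 1}" for i in range(k)])
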