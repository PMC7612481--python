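"""PRS computation, standardization and linear combination.

A PRS is the weighted allele-dosage sum ``sum_k beta_k x_k``.  Scores are
standardized to unit standard deviation in the *controls of each stratum*
(no centering: reported score means are meaningful).  Two or more PRSs can
be combined as ``alpha_0 + alpha_1 PRS_1 + alpha_2 PRS_2`` with coefficients
fitted by logistic regression on a case-control validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DataError, NumericalError
from .io_formats import CohortTable, GenotypeMatrix, WeightSet

logger = logging.getLogger(__name__)


@dataclass
class PRSVector:
    """Per-sample scores with optional per-stratum standardization record."""

    scores: pd.Series  # index: sample_id
    label: str = "PRS"
    standardization: dict | None = None  # stratum -> control SD divided out

    def __post_init__(self) -> None:
        s = self.scores
        if not isinstance(s, pd.Series):
            s = pd.Series(np.asarray(s, dtype=float))
        object.__setattr__(self, "scores", s.astype(float))

    def reindex(self, sample_ids) -> "PRSVector":
        return PRSVector(self.scores.loc[list(sample_ids)], self.label, self.standardization)


@dataclass
class CombinationWeights:
    """Affine combination coefficients for component PRSs."""

    alpha0: float
    alphas: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if not np.isfinite(a).all() or not np.isfinite(self.alpha0):
            raise DataError("non-finite combination weights")
        object.__setattr__(self, "alphas", a)


def compute_prs(gm: GenotypeMatrix, ws: WeightSet) -> PRSVector:
    """Dot product of dosages with weights (alleles assumed harmonized).

    Missing dosages are mean-imputed: with ``2 * eaf`` from the weight
    set's stored frequency when present, otherwise with the observed column
    mean.  Zero variant overlap is an error; the overlap fraction is logged.
    """
    gidx = {v: j for j, v in enumerate(gm.variant_ids)}
    wdf = ws.df
    present = wdf["variant_id"].map(gidx).notna()
    n_overlap = int(present.sum())
    if n_overlap == 0:
        raise DataError(f"no overlap between genotypes and weight set {ws.label!r}")
    frac = n_overlap / ws.m
    logger.info("compute_prs[%s]: %d/%d variants overlap (%.1f%%)",
                ws.label, n_overlap, ws.m, 100 * frac)
    wdf = wdf[present]
    cols = wdf["variant_id"].map(gidx).astype(int).to_numpy()
    X = gm.dosages[:, cols].copy()
    if "eaf" in wdf.columns and wdf["eaf"].notna().all():
        fill = 2.0 * wdf["eaf"].to_numpy(float)
    else:
        fill = np.nanmean(X, axis=0)
        fill = np.where(np.isfinite(fill), fill, 0.0)
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(fill, inds[1])
    raw = X @ wdf["weight"].to_numpy(float)
    return PRSVector(pd.Series(raw, index=pd.Index(gm.sample_ids, name="sample_id")),
                     label=ws.label)


def standardize_prs(prs: PRSVector, cohort: CohortTable) -> PRSVector:
    """Divide each stratum's scores by that stratum's control SD.

    No centering is applied, so standardized means remain interpretable
    relative to the score's natural origin.  A stratum with fewer than two
    controls is an error.  Post-condition: control SD equals 1 within every
    stratum.
    """
    df = cohort.df.set_index("sample_id")
    missing = [s for s in df.index if s not in prs.scores.index]
    if missing:
        raise DataError(f"scores missing for {len(missing)} cohort samples")
    scores = prs.scores.loc[df.index].copy()
    ctrl = cohort.control_mask
    sds: dict[str, float] = {}
    for stratum, grp in df.groupby("stratum", sort=False):
        mask = df["stratum"] == stratum
        ctrl_scores = scores[mask.to_numpy() & ctrl]
        if len(ctrl_scores) < 2:
            raise DataError(f"stratum {stratum!r} has fewer than 2 controls")
        sd = float(ctrl_scores.std(ddof=1))
        if sd == 0:
            raise DataError(f"stratum {stratum!r} has zero control SD")
        scores[mask.to_numpy()] = scores[mask.to_numpy()] / sd
        sds[stratum] = sd
    return PRSVector(scores, label=prs.label, standardization=sds)


def _component_matrix(prs_list: list[PRSVector], sample_ids) -> np.ndarray:
    return np.column_stack([p.scores.loc[list(sample_ids)].to_numpy() for p in prs_list])


def fit_combination(
    prs_list: list[PRSVector],
    cohort_val: CohortTable,
    covariates: bool = False,
    n_pcs: int = 10,
) -> CombinationWeights:
    """Fit combination coefficients by logistic regression on a validation set.

    By default only the outcome and the component PRSs enter the model;
    ``covariates=True`` additionally adjusts for principal components and
    stratum indicators.  Near-collinear components (|r| > 0.999) and
    perfect separation are errors.
    """
    if cohort_val.mode != "binary":
        raise DataError("fit_combination requires a case/control cohort")
    if len(prs_list) < 2:
        raise DataError("need at least 2 component PRSs")
    ids = cohort_val.df["sample_id"]
    X = _component_matrix(prs_list, ids)
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(len(prs_list), k=1)
    if (np.abs(corr[iu]) > 0.999).any():
        raise DataError("component PRSs are collinear (|r| > 0.999)")
    y = cohort_val.df["case"].to_numpy()
    design = [X]
    if covariates:
        pcs = cohort_val.pc_columns(n_pcs)
        if pcs:
            design.append(cohort_val.df[pcs].to_numpy(float))
        dummies = pd.get_dummies(cohort_val.df["stratum"], drop_first=True, dtype=float)
        if dummies.shape[1]:
            design.append(dummies.to_numpy())
    M = sm.add_constant(np.column_stack(design))
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, M).fit(disp=0)
    except PerfectSeparationError as exc:
        raise NumericalError(
            "perfect separation in combination fit; check for degenerate "
            "components or reduce the model"
        ) from exc
    params = res.params
    if not np.isfinite(params).all() or np.abs(params[1:]).max() > 50:
        raise NumericalError(
            "combination fit did not converge (possible perfect separation); "
            "check for degenerate components or reduce the model"
        )
    k = len(prs_list)
    return CombinationWeights(
        alpha0=float(params[0]),
        alphas=np.asarray(params[1 : 1 + k], dtype=float),
        labels=[p.label for p in prs_list],
    )


def relative_contributions(
    weights: CombinationWeights, prs_list: list[PRSVector]
) -> np.ndarray:
    """Variance-scaled coefficient share of each component.

    Contribution of component i is ``|alpha_i| SD_i / sum_k |alpha_k| SD_k``
    where SD_k is the component's score SD -- the share of the combined
    score's linear predictor attributable to each component.
    """
    sds = np.array([float(p.scores.std(ddof=1)) for p in prs_list])
    num = np.abs(weights.alphas) * sds
    return num / num.sum()


def apply_combination(
    weights: CombinationWeights, prs_list: list[PRSVector], label: str | None = None
) -> PRSVector:
    """Affine combination ``alpha_0 + sum_i alpha_i PRS_i`` sample by sample."""
    if len(prs_list) != len(weights.alphas):
        raise DataError("component count mismatch")
    idx = prs_list[0].scores.index
    X = _component_matrix(prs_list, idx)
    combined = weights.alpha0 + X @ weights.alphas
    label = label or "+".join(weights.labels)
    return PRSVector(pd.Series(combined, index=idx), label=label)


def collapse_combination(
    weights: CombinationWeights, ws_list: list[WeightSet], label: str | None = None
) -> WeightSet:
    """Collapse an affine combination of PRSs into a single scoring file.

    Per-variant weights become ``sum_i alpha_i beta_ik`` over the components
    containing variant k (components must already be allele-harmonized to a
    shared reference).  The variant count of the result is the size of the
    union of the component variant sets.
    """
    if len(ws_list) != len(weights.alphas):
        raise DataError("component count mismatch")
    frames = []
    for alpha, ws in zip(weights.alphas, ws_list):
        df = ws.df.copy()
        df["weight"] = alpha * df["weight"].to_numpy(float)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    keep_cols = [c for c in merged.columns if c != "weight"]
    agg = {c: "first" for c in keep_cols if c != "variant_id"}
    agg["weight"] = "sum"
    out = (
        merged.groupby("variant_id", sort=False, as_index=False)
        .agg(agg)
        .reindex(columns=list(merged.columns))
    )
    label = label or "+".join(weights.labels)
    return WeightSet(out, label=label)
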