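"""LD clumping and P-value-threshold selection (the C+T PRS).

Two greedy stages over summary statistics, using r-squared computed on
demand from a genotype reference panel:

1. High-LD de-duplication inside a wide window (default 1 Mb, r2 > 0.9):
   of any correlated pair the variant with the lower association P value
   survives.
2. Clumping inside a narrower window (default 250 kb, r2 > 0.1): variants
   are visited in ascending P and retained only if uncorrelated with every
   previously retained variant in the window.

Threshold selection then scores a validation case-control set at every
distinct observed P value in ``[p_min, p_max]``.  Because the selected
variant set -- and hence the AUC -- is piecewise constant in the threshold,
evaluating at observed P values is exactly equivalent to any denser grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import CohortTable, GenotypeMatrix, SummaryStats, WeightSet

logger = logging.getLogger(__name__)


@dataclass
class ClumpConfig:
    dedup_window: int = 1_000_000
    dedup_r2: float = 0.9
    clump_window: int = 250_000
    clump_r2: float = 0.1
    p_min: float = 5e-8
    p_max: float = 1e-3

    def __post_init__(self) -> None:
        for r2 in (self.dedup_r2, self.clump_r2):
            if not (0 < r2 <= 1):
                raise DataError("r2 thresholds must lie in (0, 1]")
        if self.p_min > self.p_max:
            raise DataError("p_min must not exceed p_max")


# ---------------------------------------------------------------------------
# LD sources
# ---------------------------------------------------------------------------

class PanelLD:
    """r-squared computed on demand from a genotype reference panel.

    Missing dosages are mean-imputed before correlating.  Variants absent
    from the panel are treated as uncorrelated (with a warning).
    """

    def __init__(self, gm: GenotypeMatrix):
        X = gm.dosages.copy()
        mean = np.nanmean(X, axis=0)
        inds = np.where(~np.isfinite(X))
        X[inds] = np.take(mean, inds[1])
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._X = (X - X.mean(axis=0)) / sd
        self._n = X.shape[0]
        self._index = {v: j for j, v in enumerate(gm.variant_ids)}
        self._warned: set[str] = set()

    def r2(self, a: str, b: str) -> float:
        ja, jb = self._index.get(a), self._index.get(b)
        if ja is None or jb is None:
            for v, j in ((a, ja), (b, jb)):
                if j is None and v not in self._warned:
                    logger.warning("variant %s absent from LD panel; assuming r2=0", v)
                    self._warned.add(v)
            return 0.0
        r = float(self._X[:, ja] @ self._X[:, jb]) / self._n
        return r * r


class MatrixLD:
    """r-squared looked up in an explicit correlation matrix."""

    def __init__(self, variant_ids, R: np.ndarray):
        self._index = {v: j for j, v in enumerate(variant_ids)}
        self._R = np.asarray(R, dtype=float)
        self._warned: set[str] = set()

    def r2(self, a: str, b: str) -> float:
        ja, jb = self._index.get(a), self._index.get(b)
        if ja is None or jb is None:
            for v, j in ((a, ja), (b, jb)):
                if j is None and v not in self._warned:
                    logger.warning("variant %s absent from LD source; assuming r2=0", v)
                    self._warned.add(v)
            return 0.0
        r = self._R[ja, jb]
        return float(r * r)


# ---------------------------------------------------------------------------
# Greedy passes
# ---------------------------------------------------------------------------

def _greedy_retain(stats: SummaryStats, ld, window: int, r2_max: float) -> list[str]:
    """Visit variants in ascending (P, chrom, pos); retain a variant iff no
    already-retained variant on the same chromosome within ``window`` bp has
    r2 > ``r2_max`` with it.  Returns retained variant ids in visit order.
    """
    df = stats.df.sort_values(
        ["pval", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    kept: list[tuple[str, str, int]] = []  # (id, chrom, pos)
    out: list[str] = []
    for vid, chrom, pos in zip(df["variant_id"], df["chrom"], df["pos"]):
        conflict = False
        for kid, kchrom, kpos in kept:
            if kchrom == chrom and abs(kpos - pos) <= window:
                if ld.r2(vid, kid) > r2_max:
                    conflict = True
                    break
        if not conflict:
            kept.append((vid, chrom, pos))
            out.append(vid)
    return out


def dedup_high_ld(stats: SummaryStats, ld, cfg: ClumpConfig | None = None) -> SummaryStats:
    """Remove near-duplicate variants (r2 > ``dedup_r2`` within
    ``dedup_window``), retaining the lowest-P member of each conflict.
    Output rows are ordered by (chrom, pos)."""
    cfg = cfg or ClumpConfig()
    kept = _greedy_retain(stats, ld, cfg.dedup_window, cfg.dedup_r2)
    out = stats.df[stats.df["variant_id"].isin(kept)]
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    logger.info("dedup_high_ld: %d -> %d variants", stats.m, len(out))
    return SummaryStats(out)


def greedy_clump(stats: SummaryStats, ld, cfg: ClumpConfig | None = None) -> list[str]:
    """Clump de-duplicated statistics; returns retained variant ids in
    ascending-P retention order."""
    cfg = cfg or ClumpConfig()
    return _greedy_retain(stats, ld, cfg.clump_window, cfg.clump_r2)


# ---------------------------------------------------------------------------
# Threshold grid search
# ---------------------------------------------------------------------------

def threshold_grid_select(
    stats: SummaryStats,
    genotypes_val: GenotypeMatrix,
    cohort_val: CohortTable,
    cfg: ClumpConfig | None = None,
    label: str = "PRS_CT",
):
    """Select the P-value threshold maximizing validation AUC.

    ``stats`` holds the clumped variants with their marginal weights.  For
    every candidate threshold (``p_min`` plus each distinct observed P value
    in ``(p_min, p_max]``) the PRS over variants with ``P <= t`` is scored
    in the validation genotypes and its case/control AUC computed by the
    rank statistic.  Ties in AUC break toward the smaller threshold (fewer
    variants).

    Returns ``(best_threshold, WeightSet, curve)`` where ``curve`` is a
    DataFrame with columns threshold / n_variants / auc.
    """
    from .evaluation import auc_rank  # local import to avoid a cycle

    cfg = cfg or ClumpConfig()
    if cohort_val.mode != "binary":
        raise DataError("threshold selection requires a case/control cohort")
    df = stats.df[stats.df["pval"] <= cfg.p_max]
    if len(df) == 0:
        raise DataError("empty PRS: no variant with P <= p_max")
    df = df.sort_values(["pval", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    gidx = {v: j for j, v in enumerate(genotypes_val.variant_ids)}
    present = df["variant_id"].map(gidx).notna()
    if not present.all():
        logger.warning(
            "threshold_grid_select: %d variants absent from validation genotypes",
            int((~present).sum()),
        )
        df = df[present].reset_index(drop=True)
        if len(df) == 0:
            raise DataError("empty PRS: no candidate variant in validation genotypes")
    cols = df["variant_id"].map(gidx).astype(int).to_numpy()
    X = genotypes_val.dosages[:, cols].copy()
    mean = np.nanmean(X, axis=0)
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(mean, inds[1])
    w = df["beta"].to_numpy(float)

    pheno = cohort_val.df.set_index("sample_id").loc[genotypes_val.sample_ids, "case"]
    case_mask = pheno.to_numpy() == 1

    pvals = df["pval"].to_numpy(float)
    candidates = np.unique(np.r_[cfg.p_min, pvals[(pvals > cfg.p_min) & (pvals <= cfg.p_max)]])

    score = np.zeros(X.shape[0])
    j = 0  # variants included so far (sorted by P)
    rows = []
    best = None
    for t in candidates:
        while j < len(pvals) and pvals[j] <= t:
            score = score + X[:, j] * w[j]
            j += 1
        if j == 0:
            continue
        auc = auc_rank(score[case_mask], score[~case_mask])
        rows.append((t, j, auc))
        if best is None or auc > best[2]:
            best = (t, j, auc)
    if best is None:
        raise DataError("empty PRS: no variant at or below any candidate threshold")
    t_best, k_best, _ = best
    selected = df.iloc[:k_best]
    ws = WeightSet(
        selected[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]]
        .assign(weight=selected["beta"].to_numpy(), eaf=selected["eaf"].to_numpy()),
        label=label,
    )
    curve = pd.DataFrame(rows, columns=["threshold", "n_variants", "auc"])
    return t_best, ws, curve
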