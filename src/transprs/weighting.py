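"""Re-estimation of PRS weights from summary statistics.

Two estimators, both operating on the standardized-genotype scale where the
LD matrix (a correlation matrix) and the effects are scale-consistent:

* **Joint (LD-adjusted) weights.**  Marginal effects measured in a GWAS are
  inflated by LD with neighbouring signals.  Given standardized marginal
  effects ``beta'`` and the genotype correlation matrix ``R``, the joint
  effects solve ``R gamma' = beta'``; dosage-scale weights are
  ``gamma_j = gamma'_j / sqrt(2 p_j (1 - p_j))``.  A small ridge term
  (default 1e-3) stabilizes panel-estimated ``R``.

* **Empirical Bayes cross-ancestry fusion.**  Target-ancestry estimates
  ``beta'_ASN`` are noisy but unbiased for the target population; a
  well-powered European joint estimate is precise but may be biased by
  incomplete effect transfer.  Under a normal-normal model with a common
  heterogeneity variance ``A`` across variants,

      A_hat = max(0, mean_j[(beta'_ASN_j - beta'_EUR_j)^2] - mean_j[se'_j^2])

  (method of moments), and the posterior blends the two:

      post_j = beta'_EUR_j + A_hat / (A_hat + se'_j^2) * (beta'_ASN_j - beta'_EUR_j)

  The shrinkage factor lies in [0, 1], so the posterior always sits between
  the prior mean and the target-ancestry estimate.  Dosage-scale weights
  divide by ``sqrt(2 p_j (1 - p_j))`` using the target-ancestry frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import DataError, NumericalError
from .io_formats import SummaryStats, WeightSet


@dataclass
class StandardizedEffects:
    """Marginal effects on the standardized-genotype scale.

    ``beta_std = beta * sqrt(2 p (1-p))`` and ``se_std`` the standard error
    on the same scale; carries variant identity and alleles so results can
    be emitted as weight sets.
    """

    variant_id: np.ndarray
    beta_std: np.ndarray
    se_std: np.ndarray
    eaf: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta_std", "se_std", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(arr).all():
                raise DataError(f"non-finite {name}")
            object.__setattr__(self, name, arr)
        if not ((self.eaf > 0) & (self.eaf < 1)).all():
            raise DataError("eaf must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.beta_std)

    @classmethod
    def from_summary_stats(cls, stats: SummaryStats) -> "StandardizedEffects":
        df = stats.df
        scale = np.sqrt(2 * df["eaf"].to_numpy(float) * (1 - df["eaf"].to_numpy(float)))
        return cls(
            variant_id=df["variant_id"].to_numpy(),
            beta_std=df["beta"].to_numpy(float) * scale,
            se_std=df["se"].to_numpy(float) * scale,
            eaf=df["eaf"].to_numpy(float),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            effect_allele=df["effect_allele"].to_numpy(),
            other_allele=df["other_allele"].to_numpy(),
        )

    def _weight_frame(self, dosage_weights: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "weight": dosage_weights,
                "eaf": self.eaf,
            }
        )


@dataclass
class EBPrior:
    """Cross-ancestry prior: per-variant prior means (the European
    standardized joint effects) and a common heterogeneity variance."""

    prior_mean: np.ndarray
    a_var: float

    def __post_init__(self) -> None:
        if self.a_var < 0:
            raise DataError("heterogeneity variance must be non-negative")
        object.__setattr__(self, "prior_mean", np.asarray(self.prior_mean, dtype=float))


def joint_weights(
    std: StandardizedEffects,
    R: np.ndarray,
    ridge_eps: float = 1e-3,
    label: str = "PRS_joint",
) -> WeightSet:
    """LD-adjusted joint weights: solve ``(R + ridge_eps I) gamma' = beta'``.

    ``R`` must be the genotype correlation matrix over the same variants in
    the same order.  With ``ridge_eps=0`` a singular ``R`` raises
    :class:`NumericalError` suggesting a ridge.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (std.m, std.m):
        raise DataError(f"LD matrix shape {R.shape} != ({std.m}, {std.m})")
    if not np.allclose(R, R.T, atol=1e-8):
        raise DataError("LD matrix must be symmetric")
    if ridge_eps < 0:
        raise DataError("ridge_eps must be non-negative")
    A = R + ridge_eps * np.eye(std.m)
    try:
        gamma_std = linalg.solve(A, std.beta_std, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "LD matrix is singular; pass ridge_eps > 0 to regularize"
        ) from exc
    if not np.isfinite(gamma_std).all():
        raise NumericalError(
            "joint solve produced non-finite weights; try a larger ridge_eps"
        )
    scale = np.sqrt(2 * std.eaf * (1 - std.eaf))
    return WeightSet(std._weight_frame(gamma_std / scale), label=label)


def estimate_eb_prior(
    asn: StandardizedEffects, eur_prior_mean: np.ndarray
) -> EBPrior:
    """Method-of-moments heterogeneity variance across ancestries.

    ``A_hat = max(0, mean[(beta'_ASN - beta'_EUR)^2] - mean[se'^2])``,
    clipped at zero when sampling noise explains all the disagreement.
    """
    mu = np.asarray(eur_prior_mean, dtype=float)
    if len(mu) != asn.m:
        raise DataError("prior mean length mismatch")
    if asn.m < 2:
        raise DataError("need at least 2 variants to estimate the prior variance")
    diff2 = (asn.beta_std - mu) ** 2
    a_hat = max(0.0, float(diff2.mean() - (asn.se_std**2).mean()))
    return EBPrior(prior_mean=mu, a_var=a_hat)


def eb_weights(
    asn: StandardizedEffects, prior: EBPrior, label: str = "PRS_EB"
) -> WeightSet:
    """Posterior effect sizes in the target ancestry, as dosage-scale weights.

    ``post = mu + A/(A + se'^2) * (beta'_ASN - mu)``; the dosage-scale
    weight is ``post / sqrt(2 p (1-p))`` with the target-ancestry ``p``.
    In the limits: ``se' -> 0`` gives the target estimate; ``A = 0`` gives
    the prior mean.
    """
    if len(prior.prior_mean) != asn.m:
        raise DataError("prior mean length mismatch")
    denom = prior.a_var + asn.se_std**2
    with np.errstate(invalid="ignore"):
        shrink = np.where(denom > 0, prior.a_var / np.where(denom > 0, denom, 1.0), 1.0)
    post = prior.prior_mean + shrink * (asn.beta_std - prior.prior_mean)
    scale = np.sqrt(2 * asn.eaf * (1 - asn.eaf))
    return WeightSet(asn._weight_frame(post / scale), label=label)
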