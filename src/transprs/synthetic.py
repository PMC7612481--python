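"""Synthetic multi-ancestry genotype, summary-statistic and phenotype generator.

The consortium data behind cross-ancestry breast-cancer PRS studies are
access-controlled, so this module generates stand-in data with known ground
truth: two-ancestry genotypes with Balding-Nichols allele-frequency
divergence and block-AR(1) linkage disequilibrium, marginal summary
statistics consistent with a known joint-effect vector, retrospective
case-control samples with a target odds ratio per score SD, and prospective
cohorts with a target hazard ratio per SD under censoring.

All functions are deterministic given a seed (or a ``numpy.random.Generator``).

Generative models
-----------------
* Allele frequencies: Balding-Nichols, ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``
  with ancestral frequency ``p`` and divergence ``F`` (Fst); draws clipped
  to ``[0.01, 0.99]``.
* Genotypes: Gaussian copula per haplotype.  Within an LD block, latent
  standard normals follow an AR(1) with parameter ``rho``; a haplotype
  carries the effect allele when its latent value falls below ``Phi^-1(p)``;
  the dosage is the sum over two independent haplotypes, so marginals are
  Hardy-Weinberg binomial(2, p).
* Marginal effects: on the standardized-genotype scale the expected marginal
  effects are ``beta' = R @ gamma'`` for joint effects ``gamma'`` and LD
  correlation matrix ``R``; per-variant sampling noise has standard
  deviation ``1/sqrt(n)`` on that scale.
* Case-control outcomes: rare-disease retrospective sampling under a
  logistic model with standardized-score log-odds ``ln(OR per SD)`` -- cases
  are drawn with weights ``exp(beta * z)`` (equivalently ``N(beta, 1)`` for
  a standard-normal score pool), controls from the population.
* Cohorts: exponential event times with proportional hazards on the
  standardized score, random exponential censoring plus administrative
  censoring at end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import CohortTable, GenotypeMatrix, IncidenceTable, SummaryStats

# Default scale of the simulated study, mirroring a large two-stage design:
# a case-control validation set of ~6,400/6,600 and a prospective test
# cohort of ~90,000 women accruing ~1,600 incident cases over follow-up.
DEFAULT_N_CASE = 6392
DEFAULT_N_CONTROL = 6638
DEFAULT_COHORT_N = 89898
DEFAULT_OR_PER_SD = 1.55
DEFAULT_HR_PER_SD = 1.62
DEFAULT_BASELINE_HAZARD = 0.0011   # per year; ~1,600 events per 90-100k over 15y
DEFAULT_FOLLOWUP_YEARS = 15.0
DEFAULT_CENSOR_RATE = 0.01         # per year, random loss to follow-up
DEFAULT_EFFECT_CORRELATION = 0.8   # cross-ancestry effect-size correlation


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Population models
# ---------------------------------------------------------------------------

@dataclass
class AncestryModel:
    """Population model: divergence from the ancestral pool plus LD structure.

    ``ld_blocks`` is a list of ``(block_size, rho)`` pairs whose sizes sum
    to the number of variants; within a block the latent haplotype normals
    follow an AR(1) with parameter ``rho``.
    """

    name: str
    fst: float
    ld_blocks: list[tuple[int, float]]
    ancestral_freqs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.ancestral_freqs, dtype=float)
        if not (0 <= self.fst < 1):
            raise DataError("fst must lie in [0, 1)")
        for size, rho in self.ld_blocks:
            if not (-1 < rho < 1):
                raise DataError("AR(1) rho must lie in (-1, 1)")
            if size <= 0:
                raise DataError("block sizes must be positive")
        if sum(s for s, _ in self.ld_blocks) != len(p):
            raise DataError("block sizes must sum to the number of variants")
        if not ((p > 0) & (p < 1)).all():
            raise DataError("ancestral frequencies must lie in (0, 1)")
        object.__setattr__(self, "ancestral_freqs", p)

    @property
    def m(self) -> int:
        return len(self.ancestral_freqs)


@dataclass
class TrueEffects:
    """Ground-truth joint effects on the standardized-genotype scale.

    ``gamma`` maps ancestry name -> length-``m`` effect vector;
    ``shared_correlation`` records the cross-ancestry correlation used to
    draw them.
    """

    gamma: dict[str, np.ndarray]
    shared_correlation: float = DEFAULT_EFFECT_CORRELATION

    def __post_init__(self) -> None:
        lengths = {k: len(np.asarray(v)) for k, v in self.gamma.items()}
        if len(set(lengths.values())) > 1:
            raise DataError(f"effect vectors differ in length: {lengths}")
        for k, v in self.gamma.items():
            v = np.asarray(v, dtype=float)
            if not np.isfinite(v).all():
                raise DataError(f"non-finite effects for ancestry {k!r}")
            self.gamma[k] = v

    @property
    def m(self) -> int:
        return len(next(iter(self.gamma.values())))


def simulate_true_effects(
    m: int,
    n_causal: int,
    effect_sd: float = 0.05,
    correlation: float = DEFAULT_EFFECT_CORRELATION,
    ancestries: tuple[str, str] = ("EAS", "EUR"),
    seed=None,
) -> TrueEffects:
    """Draw sparse joint effects shared across two ancestries.

    Causal variants are chosen uniformly; their standardized effects are
    bivariate normal with standard deviation ``effect_sd`` and the given
    cross-ancestry correlation (partial transferability).
    """
    rng = _rng(seed)
    idx = rng.choice(m, size=n_causal, replace=False)
    cov = effect_sd**2 * np.array([[1.0, correlation], [correlation, 1.0]])
    draws = rng.multivariate_normal([0.0, 0.0], cov, size=n_causal)
    g1 = np.zeros(m)
    g2 = np.zeros(m)
    g1[idx] = draws[:, 0]
    g2[idx] = draws[:, 1]
    return TrueEffects(
        {ancestries[0]: g1, ancestries[1]: g2}, shared_correlation=correlation
    )


def simulate_allele_freqs(model: AncestryModel, seed=None) -> np.ndarray:
    """Balding-Nichols draw of per-ancestry effect-allele frequencies.

    ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` has mean ``p`` and variance
    ``F p (1-p)``.  In the ``F -> 0`` limit the ancestral frequencies are
    returned unchanged.  Draws are clipped to ``[0.01, 0.99]``.
    """
    rng = _rng(seed)
    p = model.ancestral_freqs
    if model.fst == 0:
        return p.copy()
    scale = (1.0 - model.fst) / model.fst
    draws = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(draws, 0.01, 0.99)


def ld_matrix(ld_blocks: list[tuple[int, float]]) -> np.ndarray:
    """Block-diagonal AR(1) correlation matrix for the given LD blocks."""
    mats = []
    for size, rho in ld_blocks:
        lags = np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
        mats.append(rho ** lags if rho != 0 else np.eye(size))
    m = sum(s for s, _ in ld_blocks)
    out = np.zeros((m, m))
    off = 0
    for mat in mats:
        k = mat.shape[0]
        out[off : off + k, off : off + k] = mat
        off += k
    return out


def _ar1_normals(rng, n, ld_blocks) -> np.ndarray:
    """n x m latent normals with block-AR(1) correlation."""
    cols = []
    for size, rho in ld_blocks:
        z = np.empty((n, size))
        z[:, 0] = rng.standard_normal(n)
        if size > 1:
            eps = rng.standard_normal((n, size - 1))
            c = np.sqrt(1.0 - rho**2)
            for j in range(1, size):
                z[:, j] = rho * z[:, j - 1] + c * eps[:, j - 1]
        cols.append(z)
    return np.concatenate(cols, axis=1)


def variant_table(
    m: int, chrom: str = "1", start: int = 1_000_000, spacing: int = 20_000
) -> pd.DataFrame:
    """Deterministic variant metadata: ids, positions and unambiguous alleles."""
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    ea, oa = zip(*(alleles[i % 4] for i in range(m)))
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "effect_allele": ea,
            "other_allele": oa,
        }
    )


def simulate_genotypes(
    freqs,
    ld_blocks,
    n: int,
    seed=None,
    variants: pd.DataFrame | None = None,
    mean_info: float | None = None,
) -> GenotypeMatrix:
    """Simulate hard-call dosages with block LD via a Gaussian copula.

    Two independent haplotypes per individual; a haplotype carries the
    effect allele when its latent normal is below ``Phi^-1(p)``, so each
    variant is marginally Hardy-Weinberg.  Within a block the realized
    genotype correlation decays approximately as ``rho^lag``.

    ``mean_info`` (optional, in (0, 1]) emulates imputation uncertainty:
    per-variant info scores are drawn from a Beta distribution with that
    mean and the hard dosage is attenuated toward its expectation ``2p``
    with matching added noise, clipped to ``[0, 2]``.
    """
    rng = _rng(seed)
    p = np.asarray(freqs, dtype=float)
    thresh = stats.norm.ppf(p)
    hap1 = _ar1_normals(rng, n, ld_blocks) < thresh
    hap2 = _ar1_normals(rng, n, ld_blocks) < thresh
    dos = (hap1.astype(float) + hap2.astype(float))
    if mean_info is not None and mean_info < 1.0:
        if not (0 < mean_info <= 1):
            raise DataError("mean_info must lie in (0, 1]")
        conc = 30.0  # Beta concentration for per-variant info scores
        info = rng.beta(mean_info * conc, (1 - mean_info) * conc, size=len(p))
        var = 2 * p * (1 - p)
        noise = rng.standard_normal(dos.shape) * np.sqrt(info * (1 - info) * var)
        dos = info * dos + (1 - info) * 2 * p + noise
        dos = np.clip(dos, 0.0, 2.0)
    if variants is None:
        variants = variant_table(len(p))
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    meta = variants.set_index("variant_id")
    return GenotypeMatrix(sample_ids, variants["variant_id"].tolist(), dos, variants=meta)


# ---------------------------------------------------------------------------
# Summary statistics consistent with known joint effects
# ---------------------------------------------------------------------------

def make_summary_stats(
    gamma_std,
    freqs,
    R: np.ndarray,
    n: int,
    noise: bool = True,
    seed=None,
    variants: pd.DataFrame | None = None,
    info: float = 1.0,
) -> SummaryStats:
    """Marginal summary statistics implied by joint effects and LD.

    On the standardized-genotype scale the expected marginal effects are
    ``beta' = R @ gamma'``.  Dosage-scale estimates divide by
    ``sqrt(2 p (1-p))``; standard errors are ``1 / sqrt(n 2 p (1-p))``;
    P values are two-sided normal.  With ``noise=False`` the output is
    exactly the population value, so the joint-weight solver recovers
    ``gamma'`` to numerical precision.
    """
    rng = _rng(seed)
    gamma_std = np.asarray(gamma_std, dtype=float)
    p = np.asarray(freqs, dtype=float)
    R = np.asarray(R, dtype=float)
    m = len(gamma_std)
    if R.shape != (m, m):
        raise DataError("LD matrix shape inconsistent with effects")
    eig_min = np.linalg.eigvalsh(R).min()
    if eig_min < -1e-8:
        raise DataError(f"LD matrix is not positive semi-definite (min eig {eig_min:.3g})")
    beta_std = R @ gamma_std
    se_std = np.full(m, 1.0 / np.sqrt(n))
    if noise:
        beta_std = beta_std + rng.standard_normal(m) * se_std
    scale = np.sqrt(2 * p * (1 - p))
    beta = beta_std / scale
    se = se_std / scale
    z = beta / se
    pval = 2 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    if variants is None:
        variants = variant_table(m)
    df = variants.copy()
    df["eaf"] = p
    df["beta"] = beta
    df["se"] = se
    df["pval"] = pval
    df["info"] = info
    df["n"] = n
    return SummaryStats(df)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def binormal_scores(or_per_sd: float, n_case: int, n_control: int, seed=None):
    """Exact rare-disease retrospective score draws.

    Controls are ``N(0, 1)``; cases are ``N(ln(OR per SD), 1)`` -- the
    tilted density ``phi(z) exp(beta z) / E[exp(beta Z)]``.  Returns
    ``(case_scores, control_scores)``.
    """
    rng = _rng(seed)
    beta = np.log(or_per_sd)
    return (
        rng.standard_normal(n_case) + beta,
        rng.standard_normal(n_control),
    )


def _attach_design(df: pd.DataFrame, rng, strata, n_pcs: int, ancestry: str):
    n = len(df)
    strata = list(strata)
    df["stratum"] = [strata[i % len(strata)] for i in range(n)]
    for k in range(1, n_pcs + 1):
        df[f"pc{k}"] = rng.standard_normal(n)
    df["ancestry_group"] = ancestry
    return df


def simulate_case_control(
    scores=None,
    or_per_sd: float = DEFAULT_OR_PER_SD,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    strata=("study1", "study2"),
    seed=None,
    n_pcs: int = 10,
    ancestry: str = "EAS",
):
    """Retrospective case-control sample with a target OR per score SD.

    If ``scores`` (a pool of raw PRS values) is given, it is standardized
    and cases are resampled with weights ``exp(ln(OR) * z)`` (controls
    uniformly), the rare-disease retrospective limit of a logistic model
    whose standardized-score log-odds is ``ln(or_per_sd)``.  Without a pool,
    scores are drawn from the exact binormal limit.

    Returns ``(CohortTable, prs_series)`` where ``prs_series`` maps the new
    sample ids to raw scores (case mean exceeds control mean by about
    ``ln(OR)`` score SDs).
    """
    rng = _rng(seed)
    beta = np.log(or_per_sd)
    if scores is None:
        case_z, control_z = binormal_scores(or_per_sd, n_case, n_control, rng)
    else:
        pool = np.asarray(scores, dtype=float)
        z = (pool - pool.mean()) / pool.std()
        w = np.exp(beta * z - (beta * z).max())
        case_idx = rng.choice(len(pool), size=n_case, replace=True, p=w / w.sum())
        ctrl_idx = rng.choice(len(pool), size=n_control, replace=True)
        case_z, control_z = z[case_idx], z[ctrl_idx]
    n = n_case + n_control
    df = pd.DataFrame(
        {
            "sample_id": [f"CC{i + 1:06d}" for i in range(n)],
            "case": np.r_[np.ones(n_case, int), np.zeros(n_control, int)],
        }
    )
    df = _attach_design(df, rng, strata, n_pcs, ancestry)
    prs = pd.Series(np.r_[case_z, control_z], index=df["sample_id"], name="prs")
    return CohortTable(df), prs


def simulate_cohort(
    scores=None,
    hr_per_sd: float = DEFAULT_HR_PER_SD,
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD,
    censor_rate: float = DEFAULT_CENSOR_RATE,
    followup: float = DEFAULT_FOLLOWUP_YEARS,
    n: int = DEFAULT_COHORT_N,
    seed=None,
    n_pcs: int = 2,
    ancestry: str = "EAS",
):
    """Prospective cohort with proportional hazards on the standardized score.

    Event times are exponential with rate ``baseline_hazard *
    hr_per_sd**z``; censoring is the minimum of an exponential
    (``censor_rate``) and administrative follow-up end.  Returns
    ``(CohortTable, prs_series)``.
    """
    rng = _rng(seed)
    if scores is None:
        z = rng.standard_normal(n)
    else:
        pool = np.asarray(scores, dtype=float)
        if len(pool) < n:
            raise DataError(f"score pool smaller than cohort size ({len(pool)} < {n})")
        z = (pool[:n] - pool[:n].mean()) / pool[:n].std()
    beta = np.log(hr_per_sd)
    rate = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0 else np.full(n, np.inf)
    t_cens = np.minimum(t_cens, followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "sample_id": [f"CH{i + 1:06d}" for i in range(n)],
            "time": time,
            "event": event,
        }
    )
    df = _attach_design(df, rng, ["cohort1"], n_pcs, ancestry)
    prs = pd.Series(z, index=df["sample_id"], name="prs")
    return CohortTable(df), prs


# ---------------------------------------------------------------------------
# Incidence schedule (synthetic stand-in)
# ---------------------------------------------------------------------------

def synthetic_incidence_table(
    age_min: int = 20,
    age_max: int = 79,
    peak_incidence_per100k: float = 230.0,
    peak_age: int = 65,
) -> IncidenceTable:
    """Synthetic age-incidence schedule for testing absolute-risk code.

    A smooth log-quadratic incidence curve rising from young adulthood to a
    plateau near ``peak_age``, plus Gompertz-like all-cause mortality.  This
    is a synthetic stand-in shaped like female breast-cancer incidence in an
    East-Asian registry; it is NOT observed registry data.
    """
    ages = np.arange(age_min, age_max + 1)
    x = (ages - peak_age) / 25.0
    inc = peak_incidence_per100k * np.exp(-1.8 * x**2)
    inc[ages < 25] = np.minimum(inc[ages < 25], 5.0)
    mort = 20.0 * np.exp(0.085 * (ages - 20))
    return IncidenceTable(
        pd.DataFrame(
            {"age": ages, "incidence": inc / 1e5, "mortality": mort / 1e5}
        )
    )


# ---------------------------------------------------------------------------
# Scenario: the full two-ancestry study
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Everything a full pipeline run consumes, with ground truth attached."""

    models: dict[str, AncestryModel]
    effects: TrueEffects
    freqs: dict[str, np.ndarray]
    ld: dict[str, np.ndarray]
    sumstats: dict[str, SummaryStats]
    genotypes: dict[str, GenotypeMatrix]
    incidence: IncidenceTable


def two_ancestry_scenario(
    m: int = 120,
    n_causal: int = 12,
    fst: float = 0.08,
    block_size: int = 10,
    rho: float = 0.35,
    n_gwas: int = 40000,
    n_panel: int = 400,
    effect_sd: float = 0.045,
    effect_correlation: float = DEFAULT_EFFECT_CORRELATION,
    seed=0,
    ancestries: tuple[str, str] = ("EAS", "EUR"),
) -> Scenario:
    """Build a complete two-ancestry study with known ground truth.

    Both ancestries diverge from a shared ancestral pool at the given Fst;
    each gets its own allele frequencies, an LD panel of ``n_panel``
    genotypes, and marginal summary statistics at GWAS sample size
    ``n_gwas`` consistent with correlated joint effects.
    """
    rng = _rng(seed)
    if m % block_size:
        raise DataError("m must be a multiple of block_size")
    anc_freqs = rng.uniform(0.05, 0.95, size=m)
    blocks = [(block_size, rho)] * (m // block_size)
    variants = variant_table(m, spacing=30_000)
    models = {
        name: AncestryModel(name, fst, blocks, anc_freqs) for name in ancestries
    }
    effects = simulate_true_effects(
        m, n_causal, effect_sd, effect_correlation, ancestries, rng
    )
    R = ld_matrix(blocks)
    freqs, ld, sumstats, genotypes = {}, {}, {}, {}
    for name in ancestries:
        freqs[name] = simulate_allele_freqs(models[name], rng)
        ld[name] = R
        sumstats[name] = make_summary_stats(
            effects.gamma[name], freqs[name], R, n_gwas, noise=True, seed=rng,
            variants=variants,
        )
        genotypes[name] = simulate_genotypes(
            freqs[name], blocks, n_panel, seed=rng, variants=variants
        )
    return Scenario(
        models=models,
        effects=effects,
        freqs=freqs,
        ld=ld,
        sumstats=sumstats,
        genotypes=genotypes,
        incidence=synthetic_incidence_table(),
    )
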