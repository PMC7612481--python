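"""Incidence-constrained absolute-risk projection by PRS percentile.

Converts an OR per SD plus age-specific population incidence and competing
mortality into percentile-specific absolute risks (lifetime, 10-year,
threshold crossing) and supports birth-cohort incidence projection.

Model
-----
PRS percentile band ``k`` covers population fraction ``f_k`` and carries
relative risk ``RR_k``, the truncated-normal mean of ``exp(beta z)`` over
the band normalized so the population-average RR is exactly 1.  The
baseline hazard ``lambda_0(t)`` is chosen so that category hazards average
to the observed population incidence among women still unaffected at each
age -- the composition of survivors drifts toward low-RR bands over time,
and the constraint tracks that drift year by year:

    lambda_0(t) = lambda_pop(t) * sum_k f_k S_k(t) / sum_k f_k S_k(t) RR_k

Discretization is an annual-probability recursion over half-open one-year
age intervals ``[t, t+1)``: ``S_k(t+1) = S_k(t) (1 - lambda_0(t) RR_k)``.
With this linear decrement the f-weighted average of the per-band
cumulative risks reproduces the no-PRS population risk computed directly
from ``lambda_pop`` exactly (to rounding), for any OR per SD and any band
layout.  Competing mortality enters as an independent survival multiplier,
assumed equal across bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import IncidenceTable


@dataclass
class RiskCategories:
    """PRS percentile bands with population fractions and relative risks."""

    bands: list[tuple[float, float]]
    fractions: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if len(f) != len(self.bands) or len(rr) != len(self.bands):
            raise DataError("categories: inconsistent lengths")
        if abs(f.sum() - 1.0) > 1e-9:
            raise DataError("band fractions must sum to 1")
        if (rr < 0).any():
            raise DataError("relative risks must be non-negative")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "rr", rr)

    @property
    def k(self) -> int:
        return len(self.bands)

    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bands])


@dataclass
class RiskCurve:
    """Cumulative absolute risk by band over ``[t0, t1)``.

    ``absolute_risk[k, i]`` is band k's cumulative risk from ``t0`` through
    the end of age ``ages[i]``, conditional on being unaffected and alive
    at ``t0``.
    """

    ages: np.ndarray
    categories: RiskCategories
    baseline_hazard: pd.Series
    absolute_risk: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.absolute_risk, dtype=float)
        if (A < -1e-12).any() or (A > 1 + 1e-12).any():
            raise DataError("absolute risks must lie in [0, 1]")
        if (np.diff(A, axis=1) < -1e-12).any():
            raise DataError("absolute risk must be non-decreasing in age")
        object.__setattr__(self, "absolute_risk", A)

    def final(self) -> np.ndarray:
        """Per-band cumulative risk at the end of the horizon."""
        return self.absolute_risk[:, -1]


def make_categories(
    or_per_sd: float,
    n_bands: int = 100,
    bands: list[tuple[float, float]] | None = None,
) -> RiskCategories:
    """Percentile bands with truncated-normal relative risks.

    ``RR_k = E[e^{beta z} | z in band_k] / E[e^{beta z}]`` for
    ``z ~ N(0,1)`` and ``beta = ln(OR per SD)``, renormalized so that
    ``sum_k f_k RR_k = 1`` exactly.  Default: 100 equal 1% bands.
    """
    beta = np.log(or_per_sd)
    if bands is None:
        edges = np.linspace(0.0, 1.0, n_bands + 1)
        bands = list(zip(edges[:-1], edges[1:]))
    f = np.array([hi - lo for lo, hi in bands], dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise DataError("bands must partition (0, 1)")
    rr = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        a = stats.norm.ppf(lo) if lo > 0 else -np.inf
        b = stats.norm.ppf(hi) if hi < 1 else np.inf
        # E[e^{beta z} | band] / E[e^{beta z}]; the exp(beta^2/2) factors cancel
        rr[i] = (stats.norm.cdf(b - beta) - stats.norm.cdf(a - beta)) / (hi - lo)
    rr = rr / (f * rr).sum()
    return RiskCategories(bands=list(bands), fractions=f, rr=rr)


def constrain_baseline(inc: IncidenceTable, categories: RiskCategories) -> pd.Series:
    """Baseline hazard such that band hazards reproduce population incidence.

    Iterates ages in order, rescaling the population hazard by the
    survivor-weighted mean RR; the reconstructed population incidence
    equals the input at every age to numerical precision.
    """
    lam_pop = inc.incidence_series()
    f, rr = categories.fractions, categories.rr
    S = np.ones(categories.k)
    out = np.empty(len(lam_pop))
    for i, (age, lam) in enumerate(lam_pop.items()):
        if lam < 0:
            raise DataError("negative incidence rate")
        w = f * S
        mean_rr = (w * rr).sum() / w.sum()
        lam0 = lam / mean_rr
        if (lam0 * rr).max() >= 1:
            raise DataError(
                f"annual hazard exceeds 1 in a band at age {age}; "
                "rates too large for an annual-probability recursion"
            )
        out[i] = lam0
        S = S * (1.0 - lam0 * rr)
    return pd.Series(out, index=lam_pop.index)


def absolute_risk_curve(
    baseline_hazard: pd.Series,
    categories: RiskCategories,
    mortality: pd.Series,
    t0: int,
    t1: int,
) -> RiskCurve:
    """Cumulative absolute risk per band over ``[t0, t1)``.

    ``A_k = sum_t lambda_0(t) RR_k S_k(t) S_m(t)`` with disease-free
    survival ``S_k`` and competing-mortality survival ``S_m`` both reset to
    1 at ``t0`` (i.e. risks are conditional on being unaffected and alive
    at ``t0``).  Ages are annual, half-open.
    """
    ages = np.arange(t0, t1)
    for a in ages:
        if a not in baseline_hazard.index:
            raise DataError(f"baseline hazard missing age {a}")
        if a not in mortality.index:
            raise DataError(f"mortality missing age {a}")
    f, rr = categories.fractions, categories.rr
    Sk = np.ones(categories.k)
    Sm = 1.0
    A = np.zeros((categories.k, len(ages)))
    cum = np.zeros(categories.k)
    for i, a in enumerate(ages):
        lam0 = float(baseline_hazard.loc[a])
        mu = float(mortality.loc[a])
        cum = cum + lam0 * rr * Sk * Sm
        A[:, i] = cum
        Sk = Sk * (1.0 - lam0 * rr)
        Sm = Sm * (1.0 - mu)
    return RiskCurve(
        ages=ages, categories=categories,
        baseline_hazard=baseline_hazard.loc[ages], absolute_risk=A,
    )


def population_cumulative_risk(
    inc: IncidenceTable, t0: int, t1: int
) -> float:
    """No-PRS cumulative population risk over ``[t0, t1)`` computed directly
    from population incidence and mortality with the same annual recursion."""
    lam = inc.incidence_series()
    mu = inc.mortality_series()
    S = 1.0
    Sm = 1.0
    total = 0.0
    for a in range(t0, t1):
        total += float(lam.loc[a]) * S * Sm
        S *= 1.0 - float(lam.loc[a])
        Sm *= 1.0 - float(mu.loc[a])
    return total


def ten_year_risks(
    baseline_hazard: pd.Series,
    categories: RiskCategories,
    mortality: pd.Series,
    age: int,
    horizon: int = 10,
) -> np.ndarray:
    """Per-band risk over ``[age, age + horizon)`` (truncated at table end)."""
    t1 = min(age + horizon, int(baseline_hazard.index.max()) + 1)
    if t1 <= age:
        raise DataError(f"age {age} beyond the incidence table")
    curve = absolute_risk_curve(baseline_hazard, categories, mortality, age, t1)
    return curve.final()


def threshold_crossing(
    baseline_hazard: pd.Series,
    categories: RiskCategories,
    mortality: pd.Series,
    threshold: float,
    horizon: int = 10,
    by_age: list[int] | None = None,
) -> pd.Series:
    """Population fraction whose ``horizon``-year risk reaches ``threshold``.

    For each band, finds the first age at which the forward ``horizon``-year
    risk is at least ``threshold``; returns the cumulative population
    fraction having crossed by each age (non-decreasing in age,
    non-increasing in the threshold).
    """
    ages = baseline_hazard.index.to_numpy(int)
    first_cross = np.full(categories.k, np.iinfo(int).max)
    for a in ages:
        risks = ten_year_risks(baseline_hazard, categories, mortality, int(a), horizon)
        newly = (risks >= threshold) & (first_cross == np.iinfo(int).max)
        first_cross[newly] = a
        if (first_cross < np.iinfo(int).max).all():
            break
    report_ages = np.asarray(by_age, int) if by_age is not None else ages
    frac = [
        float(categories.fractions[first_cross <= a].sum()) for a in report_ages
    ]
    return pd.Series(frac, index=report_ages)


def project_incidence(
    inc: IncidenceTable, annual_increase: float = 0.039, years: int = 10
) -> IncidenceTable:
    """Project incidence forward for a later birth cohort.

    Incidence rates are multiplied by ``(1 + annual_increase) ** years``
    (default 3.9%/year); mortality is left unchanged.
    """
    factor = (1.0 + annual_increase) ** years
    df = inc.df.copy()
    df["incidence"] = df["incidence"] * factor
    return IncidenceTable(df)


def lifetime_risk_by_percentile(
    or_per_sd: float,
    inc: IncidenceTable,
    t0: int | None = None,
    t1: int = 80,
    n_bands: int = 100,
):
    """Callable mapping a percentile in (0,1) to lifetime risk by ``t1``.

    Builds 1%-resolution risk curves and interpolates band risks at band
    midpoints; used to attach risks to percentile positions in the
    cross-population calibration analysis.
    """
    cats = make_categories(or_per_sd, n_bands=n_bands)
    lam0 = constrain_baseline(inc, cats)
    t0 = int(inc.ages.min()) if t0 is None else t0
    t1 = min(t1, int(inc.ages.max()) + 1)
    curve = absolute_risk_curve(lam0, cats, inc.mortality_series(), t0, t1)
    mids = cats.midpoints()
    finals = curve.final()

    def risk(pct: float) -> float:
        if not (0 < pct < 1):
            raise DataError("percentile must lie in (0, 1)")
        return float(np.interp(pct, mids, finals))

    return risk
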