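"""File formats and validated in-memory containers for the PRS pipeline.

Every external file the pipeline touches goes through this module:
GWAS summary statistics (TSV), PRS scoring files (PGS-Catalog-style TSV),
genotype dosages (VCF with a DS FORMAT field, or a plain dosage-matrix TSV),
cohort phenotype tables, and age-specific incidence/mortality tables (CSV).

Containers are thin dataclasses around pandas DataFrames / numpy arrays with
strict invariant checking at construction time.  Readers reject individual
rows that violate per-row invariants (logged with counts) and raise
:class:`~transprs.errors.DataError` for structural problems.

Conventions
-----------
* Genomic positions are 1-based (VCF convention); window membership is
  ``|pos_i - pos_j| <= window`` on the same chromosome.
* Allele dosages count copies of the *effect* allele and live in ``[0, 2]``;
  missing dosages are ``NaN`` and are mean-imputed only at scoring time.
* Strand-ambiguous variants (A/T, C/G) are dropped during harmonization
  rather than resolved by allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics files
SUMSTATS_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "info", "n",
)

#: canonical column order for weight (scoring) files, internal dialect
WEIGHT_COLUMNS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight")

# PGS-Catalog scoring-file header names -> internal names
_PGS_ALIASES = {
    "rsID": "variant_id",
    "chr_name": "chrom",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "weight",
    "allelefrequency_effect": "eaf",
}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, which cannot be strand-resolved."""
    return COMPLEMENT.get(a1) == a2


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-variant marginal GWAS results for a single ancestry.

    ``df`` holds one row per variant with columns :data:`SUMSTATS_COLUMNS`:
    the marginal log-odds ``beta`` per copy of ``effect_allele``, its
    standard error ``se``, two-sided ``pval``, effect-allele frequency
    ``eaf``, imputation quality ``info`` and sample size ``n``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"summary statistics missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()[:5]
            raise DataError(f"duplicate variant_id in summary statistics: {dups}")
        if len(df):
            eaf = df["eaf"].to_numpy(float)
            if not ((eaf > 0) & (eaf < 1)).all():
                raise DataError("eaf must lie strictly inside (0, 1)")
            if not (df["se"].to_numpy(float) > 0).all():
                raise DataError("se must be positive")
            pv = df["pval"].to_numpy(float)
            if not ((pv > 0) & (pv <= 1)).all():
                raise DataError("pval must lie in (0, 1]")
            if (df["effect_allele"] == df["other_allele"]).any():
                raise DataError("effect_allele must differ from other_allele")
        object.__setattr__(self, "df", df)

    @property
    def m(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, variant_ids) -> "SummaryStats":
        """Rows for ``variant_ids``, in the given order."""
        idx = self.df.set_index("variant_id")
        return SummaryStats(idx.loc[list(variant_ids)].reset_index())


@dataclass
class WeightSet:
    """An ordered variant -> weight map defining one PRS.

    The score of an individual is ``sum_k weight_k * dosage_k`` over the
    ``m`` variants.  ``eaf`` is optional and, when present, supplies the
    frequency used for mean imputation of missing dosages.
    """

    df: pd.DataFrame
    label: str = "PRS"

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"weight set missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if len(df) == 0:
            raise DataError("empty weight set")
        if df["variant_id"].duplicated().any():
            raise DataError("duplicate variant_id in weight set")
        if not np.isfinite(df["weight"].to_numpy(float)).all():
            raise DataError("non-finite weight")
        object.__setattr__(self, "df", df)

    @property
    def m(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()


@dataclass
class GenotypeMatrix:
    """Individuals x variants matrix of expected effect-allele counts.

    ``dosages`` is ``(n_samples, m)`` float with entries in ``[0, 2]`` or
    ``NaN`` for missing.  ``variants`` optionally carries per-variant
    metadata (chrom, pos, effect_allele, other_allele) indexed like
    ``variant_ids``.
    """

    sample_ids: list
    variant_ids: list
    dosages: np.ndarray
    variants: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise DataError(
                f"dosage shape {d.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        finite = d[np.isfinite(d)]
        if finite.size and ((finite < 0).any() or (finite > 2).any()):
            raise DataError("dosages must lie in [0, 2] (or be missing)")
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "sample_ids", list(self.sample_ids))
        object.__setattr__(self, "variant_ids", list(self.variant_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)


@dataclass
class CohortTable:
    """Outcomes plus covariates for one analysis cohort.

    Exactly one outcome mode: binary case/control (column ``case`` with
    values 0/1) or time-to-event (columns ``time`` in years and ``event``
    0/1).  Covariates are numeric columns (``pc1`` ... for principal
    components); ``stratum`` labels studies/genotyping batches and
    ``ancestry_group`` labels the population.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        if "sample_id" not in df.columns:
            raise DataError("cohort table requires a sample_id column")
        binary = "case" in df.columns
        survival = "time" in df.columns and "event" in df.columns
        if binary == survival:
            raise DataError(
                "cohort table must have exactly one outcome mode: "
                "'case' or ('time', 'event')"
            )
        if survival and (df["time"].to_numpy(float) < 0).any():
            raise DataError("negative follow-up times")
        if "stratum" not in df.columns:
            df["stratum"] = "all"
        if (df["stratum"].astype(str).str.len() == 0).any():
            raise DataError("empty stratum labels")
        if "ancestry_group" not in df.columns:
            df["ancestry_group"] = "pop"
        object.__setattr__(self, "df", df)

    @property
    def mode(self) -> str:
        return "binary" if "case" in self.df.columns else "survival"

    @property
    def control_mask(self) -> np.ndarray:
        col = "case" if self.mode == "binary" else "event"
        return self.df[col].to_numpy() == 0

    def pc_columns(self, k: int | None = None) -> list[str]:
        cols = sorted(
            (c for c in self.df.columns if c.startswith("pc") and c[2:].isdigit()),
            key=lambda c: int(c[2:]),
        )
        return cols if k is None else cols[:k]


@dataclass
class IncidenceTable:
    """Age-specific annual hazards of disease incidence and competing death.

    ``df`` has contiguous single-year ``age`` bins with ``incidence`` and
    ``mortality`` expressed as events per person-year (inputs given per
    100,000 are converted on read).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("age", "incidence", "mortality"):
            if c not in self.df.columns:
                raise DataError(f"incidence table missing column {c!r}")
        df = self.df.sort_values("age").reset_index(drop=True)
        ages = df["age"].to_numpy(int)
        if len(ages) == 0:
            raise DataError("empty incidence table")
        if not (np.diff(ages) == 1).all():
            raise DataError("ages must be contiguous single-year bins")
        for c in ("incidence", "mortality"):
            if (df[c].to_numpy(float) < 0).any():
                raise DataError(f"negative {c} rate")
        object.__setattr__(self, "df", df)

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(int)

    def incidence_series(self) -> pd.Series:
        return pd.Series(self.df["incidence"].to_numpy(float), index=self.ages)

    def mortality_series(self) -> pd.Series:
        return pd.Series(self.df["mortality"].to_numpy(float), index=self.ages)


# ---------------------------------------------------------------------------
# Summary statistics I/O
# ---------------------------------------------------------------------------

def read_summary_stats(path, column_map: dict | None = None) -> SummaryStats:
    """Read a summary-statistics TSV/CSV.

    ``column_map`` maps canonical names (:data:`SUMSTATS_COLUMNS`) to the
    column names used in the file.  Rows violating per-row invariants
    (non-ACGT alleles, eaf outside (0,1), non-positive se, pval outside
    (0,1]) are rejected and counted in the log; a missing required column
    is fatal.  ``info`` defaults to 1.0 and ``n`` to NaN when absent.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    if "info" not in df.columns:
        df["info"] = 1.0
    if "n" not in df.columns:
        df["n"] = np.nan
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    df = df[list(SUMSTATS_COLUMNS)].copy()
    for c in ("eaf", "beta", "se", "pval", "info", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    n_in = len(df)
    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["eaf"].between(0, 1, inclusive="neither")
        & (df["se"] > 0)
        & df["pval"].gt(0) & df["pval"].le(1)
        & df["beta"].notna() & np.isfinite(df["beta"])
        & df["pos"].notna()
    )
    rejected = int(n_in - ok.sum())
    if rejected:
        logger.warning("%s: rejected %d/%d rows failing invariants", path, rejected, n_in)
    df = df[ok].copy()
    df["pos"] = df["pos"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return SummaryStats(df)


def write_summary_stats(stats: SummaryStats, path) -> None:
    stats.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Weight (scoring) file I/O  --  PGS-Catalog dialect
# ---------------------------------------------------------------------------

def read_weights(path) -> WeightSet:
    """Read a PGS-Catalog-style scoring TSV ('#'-prefixed header lines).

    Accepts either PGS column names (rsID/chr_name/chr_position/
    effect_allele/other_allele/effect_weight) or the internal dialect.
    Duplicate variants are fatal; an empty file is fatal.
    """
    label = "PRS"
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("pgs_name="):
                label = stripped.split("=", 1)[1]
            continue
        if line.strip():
            body.append(line)
    if len(body) <= 1:
        raise DataError(f"{path}: empty weight file")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    df = df.rename(columns=_PGS_ALIASES)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: weight file missing columns {missing}")
    keep = [c for c in list(WEIGHT_COLUMNS) + ["eaf"] if c in df.columns]
    df = df[keep].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    return WeightSet(df, label=label)


def write_weights(ws: WeightSet, path) -> None:
    """Write a scoring file that :func:`read_weights` round-trips exactly."""
    inv = {v: k for k, v in _PGS_ALIASES.items()}
    out = ws.df.rename(columns=inv)
    with open(path, "w") as fh:
        fh.write("### PGS scoring file\n")
        fh.write(f"#pgs_name={ws.label}\n")
        fh.write(f"#variants_number={ws.m}\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(obj, reference: WeightSet):
    """Align effect alleles of ``obj`` to a reference weight set.

    ``obj`` is a :class:`SummaryStats` or :class:`WeightSet`.  Only variants
    shared with the reference are kept, reordered to the reference order.
    Entries whose alleles match after swapping effect/other (optionally with
    strand complement) get ``beta := -beta`` and ``eaf := 1 - eaf``.
    Strand-ambiguous (A/T, C/G) variants are dropped and counted, as are
    variants whose allele pair is incompatible with the reference.

    The operation is idempotent: harmonizing an already-aligned object is
    the identity.
    """
    value_col = "beta" if isinstance(obj, SummaryStats) else "weight"
    ref = reference.df.set_index("variant_id")
    df = obj.df.copy()

    shared = df["variant_id"].isin(ref.index)
    n_unshared = int((~shared).sum())
    df = df[shared].copy()
    if len(df) == 0:
        raise DataError("no variants shared with the reference weight set")

    ea = df["effect_allele"].to_numpy(object)
    oa = df["other_allele"].to_numpy(object)
    ref_ea = ref.loc[df["variant_id"], "effect_allele"].to_numpy(object)
    ref_oa = ref.loc[df["variant_id"], "other_allele"].to_numpy(object)

    ambiguous = np.array([is_strand_ambiguous(a, b) for a, b in zip(ea, oa)])
    comp = np.vectorize(COMPLEMENT.get)
    same = (ea == ref_ea) & (oa == ref_oa)
    swap = (ea == ref_oa) & (oa == ref_ea)
    comp_same = (comp(ea) == ref_ea) & (comp(oa) == ref_oa)
    comp_swap = (comp(ea) == ref_oa) & (comp(oa) == ref_ea)

    flip = ~ambiguous & ~same & ~comp_same & (swap | comp_swap)
    keep = ~ambiguous & (same | comp_same | flip)
    n_ambiguous = int(ambiguous.sum())
    n_incompatible = int((~keep & ~ambiguous).sum())
    if n_unshared or n_ambiguous or n_incompatible:
        logger.warning(
            "harmonize_alleles: dropped %d unshared, %d strand-ambiguous, "
            "%d allele-incompatible variants",
            n_unshared, n_ambiguous, n_incompatible,
        )

    df.loc[flip, value_col] = -df.loc[flip, value_col]
    if "eaf" in df.columns:
        df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    df.loc[keep, "effect_allele"] = ref_ea[keep]
    df.loc[keep, "other_allele"] = ref_oa[keep]
    df = df[keep]

    # reference order
    order = {v: i for i, v in enumerate(reference.variant_ids)}
    df = df.sort_values("variant_id", key=lambda s: s.map(order)).reset_index(drop=True)
    if isinstance(obj, SummaryStats):
        return SummaryStats(df)
    return WeightSet(df, label=obj.label)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read dosages from a VCF (DS FORMAT field, GT fallback) or a TSV matrix.

    The TSV layout is variants x samples: a ``variant_id`` first column and
    one column per sample; ``NA``/empty cells are missing.  Dosages outside
    ``[0, 2]`` are fatal.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise DataError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DataError("cyvcf2 is required for VCF input") from exc
    try:
        vcf = VCF(path)
        samples = list(vcf.samples)
        rows, ids, meta = [], [], []
        for v in vcf:
            if len(v.ALT) != 1:
                raise DataError(f"multi-allelic site at {v.CHROM}:{v.POS} not supported")
            ds = None
            try:
                arr = v.format("DS")
                if arr is not None:
                    ds = np.asarray(arr, dtype=float).reshape(-1)
            except Exception:
                ds = None
            if ds is None:
                gts = np.asarray(v.genotype.array())[:, :2].astype(float)
                gts[gts < 0] = np.nan
                ds = gts.sum(axis=1)
            ds = np.where(np.isfinite(ds), ds, np.nan)
            rows.append(ds)
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            ids.append(vid)
            meta.append((vid, str(v.CHROM), int(v.POS), v.ALT[0], v.REF))
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"{path}: failed to parse VCF ({exc})") from exc
    if not rows:
        raise DataError(f"{path}: no variant records")
    dosages = np.vstack(rows).T
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    ).set_index("variant_id")
    return GenotypeMatrix(samples, ids, dosages, variants=variants)


def _read_genotype_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise DataError(f"{path}: empty genotype TSV")
    n_fields = lines[0].count("\t") + 1
    for i, line in enumerate(lines[1:], 2):
        if line.count("\t") + 1 != n_fields:
            raise DataError(
                f"{path}:{i}: truncated or ragged row "
                f"({line.count(chr(9)) + 1} fields, expected {n_fields})"
            )
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"{path}: failed to parse genotype TSV ({exc})") from exc
    if df.columns[0] != "variant_id":
        raise DataError(f"{path}: first column must be 'variant_id'")
    ids = df["variant_id"].astype(str).tolist()
    samples = list(df.columns[1:])
    if not samples:
        raise DataError(f"{path}: no sample columns")
    try:
        dosages = df[samples].astype(float).to_numpy().T
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric dosage ({exc})") from exc
    return GenotypeMatrix(samples, ids, dosages)


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)
    df.insert(0, "variant_id", gm.variant_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with per-sample DS dosages.

    The effect allele is written as ALT so that a round trip through
    :func:`read_genotypes` reproduces the dosage matrix.
    """
    if gm.variants is not None:
        meta = gm.variants
    else:
        meta = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, gm.m + 1) * 1000,
                "effect_allele": "G",
                "other_allele": "A",
            },
            index=pd.Index(gm.variant_ids, name="variant_id"),
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        contigs = pd.unique(meta["chrom"].astype(str))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, gm.sample_ids)) + "\n")
        for j, vid in enumerate(gm.variant_ids):
            row = meta.loc[vid]
            vals = [
                "." if not np.isfinite(d) else f"{d:g}" for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def read_cohort(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Incidence I/O
# ---------------------------------------------------------------------------

def read_incidence(path, per: float = 100000.0) -> IncidenceTable:
    """Read a CSV ``age,incidence_per100k,mortality_per100k``.

    Rates are converted to annual hazards by dividing by ``per``; ages must
    form contiguous single-year bins.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    age_c = cols.get("age")
    inc_c = cols.get("incidence_per100k", cols.get("incidence"))
    mor_c = cols.get("mortality_per100k", cols.get("mortality"))
    if age_c is None or inc_c is None or mor_c is None:
        raise DataError(f"{path}: need columns age, incidence_per100k, mortality_per100k")
    out = pd.DataFrame(
        {
            "age": df[age_c].astype(int),
            "incidence": df[inc_c].astype(float) / per,
            "mortality": df[mor_c].astype(float) / per,
        }
    )
    return IncidenceTable(out)


def write_incidence(inc: IncidenceTable, path, per: float = 100000.0) -> None:
    out = pd.DataFrame(
        {
            "age": inc.df["age"],
            "incidence_per100k": inc.df["incidence"] * per,
            "mortality_per100k": inc.df["mortality"] * per,
        }
    )
    out.to_csv(path, index=False)
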