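"""Reading, validation, harmonisation and standardisation of GWAS/eQTL summary statistics.

Summary statistics arrive as tab-delimited tables with one row per variant
(chromosome, position, alleles, effect size, standard error, p-value, MAF,
sample size).  Before two studies can be colocalised their variants must be
matched on genomic position with alleles reconciled (flipping the effect sign
when ref/alt are swapped), and for quantitative traits the effect sizes must
be placed on a common scale by dividing by the estimated trait standard
deviation (sdY).  eGenes — genes with at least one significant eQTL — are
selected per study by Bonferroni-correcting each gene's minimum p-value and
applying Benjamini-Hochberg FDR across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariantKey",
    "SumStatsTable",
    "StudyMeta",
    "EGene",
    "HarmonisationReport",
    "NoOverlapError",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "harmonise_pair",
    "estimate_sdY",
    "standardise_effects",
    "select_egenes",
]

#: default column-name mapping for tab-delimited summary statistics
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "CHR",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "maf": "MAF",
    "n": "N",
}

_REQUIRED = ("chrom", "pos", "ref", "alt", "beta", "se", "pvalue", "maf")

_COLUMNS = ["chrom", "pos", "ref", "alt", "beta", "se", "pvalue", "maf", "n"]


class VariantKey(NamedTuple):
    """Identity of a biallelic variant; ``alt`` is the effect allele."""

    chrom: str
    pos: int
    ref: str
    alt: str


class NoOverlapError(Exception):
    """Two summary-statistic tables share no reconcilable variants."""


@dataclass
class StudyMeta:
    """eQTL study design covariates used by the enrichment analyses."""

    study_id: str
    cell_type: str
    granularity: str  # bulk | sorted | single-cell
    composition: str  # controls | patients_and_controls
    stimulation: str  # resting | stimulated
    ancestry: str = "EUR"
    n: int = 100

    _GRAN = {"bulk", "sorted", "single-cell"}
    _COMP = {"controls", "patients_and_controls"}
    _STIM = {"resting", "stimulated"}

    def __post_init__(self) -> None:
        if self.granularity not in self._GRAN:
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.composition not in self._COMP:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.stimulation not in self._STIM:
            raise ValueError(f"unknown stimulation {self.stimulation!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class EGene:
    """A gene with study-wide significant eQTL evidence."""

    gene_id: str
    tss: tuple[str, int, str]  # (chrom, pos, strand)
    biotype: str
    study_id: str
    p_bonf: float
    q_value: float


@dataclass
class SumStatsTable:
    """Per-variant association statistics for one trait in one study.

    ``data`` holds columns chrom, pos, ref, alt, beta, se, pvalue, maf, n.
    Variant keys are unique within a table.
    """

    study_id: str
    trait_type: str  # quantitative | case-control
    data: pd.DataFrame
    validation_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(
                self.data["chrom"], self.data["pos"], self.data["ref"], self.data["alt"]
            )
        ]

    def restricted_to(self, keys: Sequence[VariantKey]) -> "SumStatsTable":
        """Rows for ``keys``, in the given order."""
        idx = pd.MultiIndex.from_frame(self.data[["chrom", "pos", "ref", "alt"]])
        df = self.data.set_index(idx)
        sub = df.loc[[tuple(k) for k in keys]].reset_index(drop=True)
        return SumStatsTable(self.study_id, self.trait_type, sub)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating invariants; count reasons."""
    report: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        nonlocal df
        bad = int(mask.sum())
        if bad:
            report[reason] = report.get(reason, 0) + bad
            df = df[~mask]
        return df

    for col in ("pos", "beta", "se", "pvalue", "maf", "n"):
        df = drop(~np.isfinite(df[col].astype(float)), f"nonfinite_{col}")
    df = drop(df["pos"].astype(int) < 1, "invalid_pos")
    df = drop(df["se"].astype(float) <= 0, "invalid_se")
    p = df["pvalue"].astype(float)
    df = drop((p <= 0) | (p > 1), "invalid_pvalue")
    maf = df["maf"].astype(float)
    df = drop((maf <= 0) | (maf > 0.5), "invalid_maf")
    df = drop(df["n"].astype(float) < 1, "invalid_n")
    df = drop(df["ref"].astype(str) == df["alt"].astype(str), "ref_equals_alt")
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep="first")
    df = drop(dup, "duplicate_variant")
    report["n_dropped"] = sum(v for k, v in report.items() if k != "n_dropped")
    return df, report


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    study_id: str = "study",
    trait_type: str = "quantitative",
    default_n: float | None = None,
) -> SumStatsTable:
    """Read a tab-delimited summary-statistics file into a validated table.

    ``dialect`` maps canonical field names (chrom, pos, ..., n) to the file's
    column headers; unspecified fields fall back to :data:`DEFAULT_DIALECT`.
    Rows violating field invariants (se <= 0, p outside (0,1], MAF outside
    (0, 0.5], duplicate variant keys ...) are dropped and counted in the
    table's ``validation_report``.  When the n column is absent,
    ``default_n`` (e.g. study-level N from :class:`StudyMeta`) is broadcast.
    """
    dl = dict(DEFAULT_DIALECT)
    if dialect:
        dl.update(dialect)
    raw = pd.read_csv(path, sep="\t", dtype={dl["chrom"]: str})
    for fieldname in _REQUIRED:
        if dl[fieldname] not in raw.columns:
            raise ValueError(
                f"required column {dl[fieldname]!r} (field {fieldname!r}) missing from {path}"
            )
    df = pd.DataFrame(
        {
            canon: raw[dl[canon]]
            for canon in _REQUIRED
        }
    )
    if dl["n"] in raw.columns:
        df["n"] = raw[dl["n"]]
    elif default_n is not None:
        df["n"] = default_n
    else:
        raise ValueError(f"column {dl['n']!r} missing and no default_n given")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    df, report = _validate_frame(df)
    if len(df) == 0:
        raise ValueError(f"no valid rows remain after filtering {path}")
    return SumStatsTable(study_id, trait_type, df.reset_index(drop=True), report)


@dataclass
class HarmonisationReport:
    n_shared: int
    n_flipped: int
    n_dropped: int


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _is_palindromic(ref: str, alt: str) -> bool:
    return ref == alt.translate(_COMPLEMENT)[::-1]


def harmonise_pair(
    a: SumStatsTable,
    b: SumStatsTable,
    drop_palindromic: bool = False,
) -> tuple[SumStatsTable, SumStatsTable, list[VariantKey], HarmonisationReport]:
    """Align two tables on shared variants, flipping swapped alleles.

    Variants are matched on (chrom, pos).  When b carries the same alleles
    with ref/alt swapped, b's beta sign is flipped and its alleles recoded to
    a's orientation.  Irreconcilable allele pairs are excluded.  Palindromic
    (A/T, C/G) variants are retained by default and matched on allele set;
    set ``drop_palindromic`` to exclude them.

    Returns the two tables restricted to the shared set in identical order,
    the shared variant keys (in a's orientation), and a report.
    Raises :class:`NoOverlapError` when no variant survives.
    """
    da = a.data.set_index(["chrom", "pos"])
    db = b.data.set_index(["chrom", "pos"])
    common = da.index.intersection(db.index)

    keys: list[VariantKey] = []
    rows_a, rows_b = [], []
    n_flipped = n_dropped = 0
    for loc in common:
        ra = da.loc[loc]
        rb = db.loc[loc]
        if isinstance(ra, pd.DataFrame) or isinstance(rb, pd.DataFrame):
            # multiple alleles at one position: skip, not reconcilable here
            n_dropped += 1
            continue
        ref_a, alt_a = ra["ref"], ra["alt"]
        ref_b, alt_b = rb["ref"], rb["alt"]
        if drop_palindromic and _is_palindromic(ref_a, alt_a):
            n_dropped += 1
            continue
        if (ref_a, alt_a) == (ref_b, alt_b):
            flip = False
        elif (ref_a, alt_a) == (alt_b, ref_b):
            flip = True
        else:
            n_dropped += 1
            continue
        rb = rb.copy()
        if flip:
            rb["beta"] = -rb["beta"]
            rb["maf"] = rb["maf"]  # MAF is fold-invariant
            rb["ref"], rb["alt"] = ref_a, alt_a
            n_flipped += 1
        keys.append(VariantKey(str(loc[0]), int(loc[1]), str(ref_a), str(alt_a)))
        ra = ra.copy()
        ra["chrom"], ra["pos"] = loc
        rb["chrom"], rb["pos"] = loc
        rows_a.append(ra)
        rows_b.append(rb)

    if not keys:
        raise NoOverlapError(f"no shared variants between {a.study_id} and {b.study_id}")

    fa = pd.DataFrame(rows_a).reset_index(drop=True)[_COLUMNS]
    fb = pd.DataFrame(rows_b).reset_index(drop=True)[_COLUMNS]
    report = HarmonisationReport(len(keys), n_flipped, n_dropped)
    return (
        SumStatsTable(a.study_id, a.trait_type, fa),
        SumStatsTable(b.study_id, b.trait_type, fb),
        keys,
        report,
    )


def estimate_sdY(se, maf, n) -> float:
    """Estimate the trait variance sdY² from summary statistics.

    With v_i = 2 n_i f_i (1 - f_i) and w_i = 1/SE_i², returns the
    no-intercept least-squares slope of v_i on w_i,

        sdY² = Σ v_i w_i / Σ w_i²,

    which recovers the phenotypic variance of a quantitative trait from the
    per-variant standard errors and allele frequencies (v_i/ n ≈ genotype
    variance; SE_i² ≈ sdY² / v_i).
    """
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if se.size < 2:
        raise ValueError("estimate_sdY needs at least 2 records")
    if np.any(se <= 0) or np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("invalid se or maf")
    v = 2.0 * n * maf * (1.0 - maf)
    w = 1.0 / se**2
    sdy_sq = float(np.sum(v * w) / np.sum(w**2))
    if not math.isfinite(sdy_sq) or sdy_sq <= 0:
        raise ValueError(f"non-finite or non-positive sdY^2 estimate: {sdy_sq}")
    return sdy_sq


def estimate_sdY_from_table(table: SumStatsTable) -> float:
    return estimate_sdY(table.data["se"], table.data["maf"], table.data["n"])


def standardise_effects(
    table: SumStatsTable, sdY_sq: float, exponent: float = 0.5
) -> SumStatsTable:
    """Rescale beta and se to a unit-variance trait.

    Both are divided by sdY²**exponent (default 0.5, i.e. by the trait SD),
    leaving z-scores and p-values untouched.
    """
    if sdY_sq <= 0:
        raise ValueError("sdY_sq must be > 0")
    scale = sdY_sq**exponent
    df = table.data.copy()
    df["beta"] = df["beta"] / scale
    df["se"] = df["se"] / scale
    return SumStatsTable(table.study_id, table.trait_type, df, dict(table.validation_report))


def select_egenes(
    per_gene_tables: Mapping[str, SumStatsTable],
    fdr_target: float = 0.01,
    annotation: Mapping[str, tuple] | None = None,
    biotypes: Mapping[str, str] | None = None,
) -> list[EGene]:
    """Select eGenes at a Benjamini-Hochberg FDR threshold.

    Each gene's minimum eQTL p-value is Bonferroni-corrected by its SNP count
    (capped at 1); BH q-values are computed across genes and genes with
    q < ``fdr_target`` are returned sorted by q then gene id.  ``annotation``
    optionally maps gene_id -> (chrom, tss, strand).
    """
    genes = sorted(per_gene_tables)
    if not genes:
        return []
    p_bonf = np.empty(len(genes))
    for i, g in enumerate(genes):
        t = per_gene_tables[g]
        if len(t) == 0:
            raise ValueError(f"empty table for gene {g}")
        p_bonf[i] = min(1.0, float(t.data["pvalue"].min()) * len(t))
    _, qvals, _, _ = multipletests(p_bonf, method="fdr_bh")
    out = []
    for g, pb, q in zip(genes, p_bonf, qvals):
        if q < fdr_target:
            tss = tuple(annotation[g]) if annotation and g in annotation else ("NA", -1, "+")
            bt = biotypes[g] if biotypes and g in biotypes else "protein_coding"
            out.append(EGene(g, tss, bt, per_gene_tables[g].study_id, float(pb), float(q)))
    out.sort(key=lambda e: (e.q_value, e.gene_id))
    return out
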