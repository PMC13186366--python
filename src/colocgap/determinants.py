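"""Regression analyses of what predicts colocalisation.

Lead-variant properties (MAF, distance to the nearest TSS, GWAS p, enhancer
overlap) and eQTL study design (cell type, granularity, sample composition,
stimulation) are related to per-test colocalisation outcomes by logistic
regression.  Because many tests share one GWAS peak, inference uses
cluster-robust (sandwich) standard errors aggregated within peaks, with the
G/(G-1) small-sample factor; per-family Bonferroni adjustment is applied by
the enrichment wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .peaks import Peak
from .sumstats import StudyMeta

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentEstimate",
    "build_determinant_design",
    "fit_cluster_logistic",
    "celltype_enrichment",
    "design_enrichment",
    "estimates_to_frame",
]


@dataclass
class EnrichmentEstimate:
    term: str
    log_or: float
    se_robust: float
    pvalue: float
    p_adj: float = np.nan
    reference: str = ""
    unreliable: bool = False


def estimates_to_frame(estimates: Sequence[EnrichmentEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "log_or": e.log_or,
                "se": e.se_robust,
                "p": e.pvalue,
                "p_adj": e.p_adj,
                "reference": e.reference,
                "unreliable": e.unreliable,
            }
            for e in estimates
        ]
    )


def _interval_overlap(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    """0-based half-open overlap of a 1-based point: start <= pos-1 < end."""
    z = pos - 1
    return any(s <= z < e for s, e in intervals)


def build_determinant_design(
    peaks: Sequence[Peak],
    tests: pd.DataFrame,
    lead_maf: Mapping[str, float],
    tss_positions: Mapping[str, Sequence[int]],
    enhancers: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """One design row per coloc test with lead-variant covariates.

    ``tests`` needs columns peak_id, significant (plus any carried-through
    identifiers).  ``lead_maf`` maps peak_id -> lead MAF; ``tss_positions``
    maps chromosome -> sorted TSS coordinates; ``enhancers`` maps chromosome
    -> 0-based half-open intervals of active enhancers.  Covariates: maf,
    log10_p of the lead, log10 distance (kb) to the nearest TSS with the
    distance floored at 1 bp, and a 0/1 enhancer-overlap indicator.
    """
    pk = {p.peak_id: p for p in peaks}
    missing_chrom = sorted(
        {pk[pid].lead.chrom for pid in tests["peak_id"] if pid in pk}
        - set(tss_positions)
    )
    if missing_chrom:
        raise ValueError(f"no TSS annotation for chromosomes: {missing_chrom}")
    rows = []
    for _, t in tests.iterrows():
        p = pk.get(t["peak_id"])
        if p is None:
            continue
        if p.peak_id not in lead_maf:
            raise ValueError(f"no MAF for peak lead {p.peak_id}")
        tss = np.asarray(tss_positions[p.lead.chrom])
        dist = max(1, int(np.min(np.abs(tss - p.lead.pos))))
        row = dict(t)
        row.update(
            {
                "maf": float(lead_maf[p.peak_id]),
                "log10_dist_kb": float(np.log10(dist / 1000.0)),
                "log10_p": float(np.log10(p.lead_p)),
                "enhancer": int(
                    _interval_overlap(p.lead.pos, enhancers.get(p.lead.chrom, []))
                )
                if enhancers is not None
                else 0,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


class SeparationWarning(UserWarning):
    """A covariate (near-)perfectly predicts the outcome."""


def fit_cluster_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    cluster_on: str,
) -> list[EnrichmentEstimate]:
    """Logistic regression with peak-clustered sandwich standard errors.

    Constant covariates are dropped with a warning; columns aliased with the
    remaining design (rank deficiency) are likewise dropped, mirroring what
    R's glm reports as NA coefficients.  Perfect separation is detected from
    fitted probabilities pinned at 0/1 and flags the estimates unreliable
    rather than failing.
    """
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    groups = data[cluster_on]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 clusters for cluster-robust errors")

    kept: list[str] = []
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for c in covariates:
        col = data[c].astype(float)
        if col.nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped", UserWarning)
            continue
        trial = np.column_stack([X.values, col.values])
        if np.linalg.matrix_rank(trial) <= X.shape[1]:
            warnings.warn(
                f"covariate {c!r} is collinear with the design; dropped", UserWarning
            )
            continue
        X[c] = col
        kept.append(c)
    if not kept:
        return []

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IRLS convergence chatter under separation
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": np.asarray(groups), "use_correction": True}
        )
    fitted = res.fittedvalues
    separated = bool(np.any((fitted < 1e-8) | (fitted > 1 - 1e-8))) or bool(
        np.any(np.abs(res.params[kept]) > 15)
    )
    if separated:
        warnings.warn("possible separation: estimates flagged unreliable", SeparationWarning)
    return [
        EnrichmentEstimate(
            term=c,
            log_or=float(res.params[c]),
            se_robust=float(res.bse[c]),
            pvalue=float(res.pvalues[c]),
            unreliable=separated,
        )
        for c in kept
    ]


def celltype_enrichment(
    tests: pd.DataFrame,
    group_col: str,
    reference: str,
    cluster_on: str = "peak_id",
    outcome: str = "significant",
    count_transform: str = "log10",
) -> list[EnrichmentEstimate]:
    """Per-group colocalisation enrichment relative to a reference group.

    Fits a cluster-robust logistic regression with an indicator per
    non-reference group plus a per-group test-count covariate
    (log10-transformed by default; ``count_transform='identity'`` for the
    raw count).  The count covariate is group-constant and therefore aliased
    with the indicators; it is entered and dropped if collinear, as in the
    equivalent R fit.  P-values are Bonferroni-adjusted by the number of
    non-reference groups.
    """
    df = tests.copy()
    counts = df[group_col].value_counts()
    empty_ok = counts[counts > 0].index
    df = df[df[group_col].isin(empty_ok)]
    if reference not in set(df[group_col]):
        raise ValueError(f"reference group {reference!r} absent")
    groups = sorted(g for g in df[group_col].unique() if g != reference)
    if not groups:
        return []
    for g in groups:
        df[f"ct_{g}"] = (df[group_col] == g).astype(float)
    cnt = df[group_col].map(counts).astype(float)
    df["n_tests_in_group"] = np.log10(cnt) if count_transform == "log10" else cnt
    covs = [f"ct_{g}" for g in groups] + ["n_tests_in_group"]
    ests = fit_cluster_logistic(df, outcome, covs, cluster_on)
    out = []
    m = len(groups)
    for e in ests:
        if not e.term.startswith("ct_"):
            continue
        e.term = e.term[3:]
        e.p_adj = min(1.0, e.pvalue * m)
        e.reference = reference
        out.append(e)
    return out


def design_enrichment(
    tests: pd.DataFrame,
    meta: Mapping[str, StudyMeta],
    cluster_on: str = "peak_id",
    outcome: str = "significant",
    exclude_cell_types: Sequence[str] = ("whole blood",),
    baselines: Mapping[str, str] | None = None,
) -> list[EnrichmentEstimate]:
    """Joint enrichment of study-design covariates (granularity, composition,
    stimulation) with cell-type indicators, excluding whole blood.

    Baselines default to NK cells, sorted cells, controls and resting cells.
    Single-level factors are dropped with a warning.  Cluster-robust SEs on
    peaks; Bonferroni adjustment across the design terms reported.
    """
    base = {
        "cell_type": "NK",
        "granularity": "sorted",
        "composition": "controls",
        "stimulation": "resting",
    }
    if baselines:
        base.update(baselines)
    df = tests.copy()
    for fieldname in ("cell_type", "granularity", "composition", "stimulation"):
        df[fieldname] = df["study_id"].map(lambda s: getattr(meta[s], fieldname))
    df = df[~df["cell_type"].isin(exclude_cell_types)].copy()
    if len(df) == 0:
        raise ValueError("no tests remain after cell-type exclusion")

    covs: list[str] = []
    for g in sorted(df["cell_type"].unique()):
        if g == base["cell_type"]:
            continue
        df[f"ct_{g}"] = (df["cell_type"] == g).astype(float)
        covs.append(f"ct_{g}")
    design_terms = {
        "single_cell": ("granularity", "single-cell"),
        "patients_and_controls": ("composition", "patients_and_controls"),
        "stimulated": ("stimulation", "stimulated"),
    }
    fitted_terms = []
    for term, (fieldname, level) in design_terms.items():
        if df[fieldname].nunique() < 2:
            warnings.warn(f"factor {fieldname!r} single-levelled; term dropped", UserWarning)
            continue
        df[term] = (df[fieldname] == level).astype(float)
        covs.append(term)
        fitted_terms.append(term)
    ests = fit_cluster_logistic(df, outcome, covs, cluster_on)
    out = []
    m = max(1, len(fitted_terms))
    for e in ests:
        if e.term in fitted_terms:
            e.p_adj = min(1.0, e.pvalue * m)
            e.reference = base[design_terms[e.term][0]]
            out.append(e)
        elif e.term.startswith("ct_"):
            e.term = e.term[3:]
            e.reference = base["cell_type"]
            out.append(e)
    return out
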