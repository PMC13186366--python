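"""Analyses of GWAS peaks colocalising with multiple genes.

The central object is the peak-gene matrix: one row per
(peak, gene, eQTL study) colocalisation test carrying the test's cell type,
PP(H4) and significance flag.  From it we derive the distribution of
distinct colocalised genes per peak, a randomisation null (permuting PP(H4)
within peaks to model random false positives), threshold-sensitivity curves,
cross-mappability filtering, matched case/control gene pairs for
co-regulation contrasts, and enhancer-link stratification with a
peak-random-intercept logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .determinants import fit_cluster_logistic

__all__ = [
    "MATRIX_COLUMNS",
    "CrossmapEntry",
    "EnhancerLink",
    "genes_per_peak",
    "randomisation_null",
    "threshold_sensitivity",
    "crossmap_filter",
    "build_control_pairs",
    "coregulation_contrasts",
    "same_celltype_pair_enrichment",
    "lead_snp_r2",
    "enhancer_link_rates",
]

#: columns of a peak-gene matrix (one row per coloc test)
MATRIX_COLUMNS = ["peak_id", "gene_id", "study_id", "cell_type", "pp_h4", "significant"]


@dataclass(frozen=True)
class CrossmapEntry:
    """Symmetrised k-mer cross-alignment count between two genes."""

    gene_a: str
    gene_b: str
    count: float


@dataclass(frozen=True)
class EnhancerLink:
    """Predicted enhancer-gene regulatory link with its E2G probability."""

    cell_type: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str
    score: float


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MATRIX_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"peak-gene matrix missing columns: {missing}")
    return matrix


def genes_per_peak(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """Distinct significant genes per peak, the count histogram, and the
    fraction of peaks with >= 2 among those with >= 1."""
    m = _check_matrix(matrix)
    counts = (
        m[m["significant"]].groupby("peak_id")["gene_id"].nunique()
        .reindex(m["peak_id"].unique(), fill_value=0)
        .sort_index()
    )
    hist = counts.value_counts().sort_index()
    with_any = counts[counts >= 1]
    multi_fraction = float((with_any >= 2).mean()) if len(with_any) else 0.0
    return counts, hist, multi_fraction


def _cum_mean_distinct(m: pd.DataFrame, study_order: Sequence[str], alpha: float | None) -> np.ndarray:
    """Cumulative mean over peaks of distinct significant genes as studies accrue."""
    peaks = m["peak_id"].unique()
    seen: dict[str, set] = {p: set() for p in peaks}
    sig = m["significant"] if alpha is None else (m["pp_h4"] > alpha)
    msig = m[sig.values]
    by_study = dict(tuple(msig.groupby("study_id")))
    curve = np.empty(len(study_order))
    for k, s in enumerate(study_order):
        if s in by_study:
            for pid, gid in zip(by_study[s]["peak_id"], by_study[s]["gene_id"]):
                seen[pid].add(gid)
        curve[k] = np.mean([len(v) for v in seen.values()])
    return curve


def randomisation_null(
    matrix: pd.DataFrame,
    alpha: float,
    study_order_iters: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Observed vs within-peak-permuted accumulation of colocalised genes.

    Per iteration a random ordering of the eQTL studies is drawn and the
    cumulative mean (over peaks) of distinct significant genes after adding
    each study is computed twice: on the observed data and after permuting
    the PP(H4) values uniformly at random across the (gene, study) tests
    within each peak, re-calling significance at the same fixed ``alpha``.
    Returns both curve stacks and the medians of the iteration-final means.
    """
    m = _check_matrix(matrix).reset_index(drop=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    studies = sorted(m["study_id"].unique())
    if len(studies) < 2:
        raise ValueError("need >= 2 studies for a randomisation null")
    obs_curves, perm_curves = [], []
    for _ in range(study_order_iters):
        order = list(rng.permutation(studies))
        obs_curves.append(_cum_mean_distinct(m, order, alpha))
        perm = m.copy()
        perm["pp_h4"] = (
            perm.groupby("peak_id")["pp_h4"].transform(lambda s: rng.permutation(s.values))
        )
        perm_curves.append(_cum_mean_distinct(perm, order, alpha))
    obs = np.vstack(obs_curves)
    per = np.vstack(perm_curves)
    return {
        "observed_curves": obs,
        "permuted_curves": per,
        "observed_final": obs[:, -1],
        "permuted_final": per[:, -1],
        "observed_final_median": float(np.median(obs[:, -1])),
        "permuted_final_median": float(np.median(per[:, -1])),
        "study_count": len(studies),
    }


def threshold_sensitivity(matrix: pd.DataFrame, alphas: Sequence[float]) -> pd.DataFrame:
    """Counts of peaks with >= 1/2/3 colocalising genes over a PP(H4) grid."""
    m = _check_matrix(matrix)
    if np.any((np.asarray(alphas) < 0) | (np.asarray(alphas) > 1)):
        raise ValueError("alphas must lie in [0, 1]")
    rows = []
    for a in alphas:
        counts = m[m["pp_h4"] > a].groupby("peak_id")["gene_id"].nunique()
        n1 = int((counts >= 1).sum())
        n2 = int((counts >= 2).sum())
        n3 = int((counts >= 3).sum())
        rows.append(
            {
                "alpha": a,
                "peaks_ge1": n1,
                "peaks_ge2": n2,
                "peaks_ge3": n3,
                "multi_fraction": (n2 / n1) if n1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def crossmap_filter(
    matrix: pd.DataFrame, crossmap: Sequence[CrossmapEntry]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude one gene of each cross-mappable significant pair per peak.

    Cross-mappability counts are symmetrised by pairwise max.  Within each
    peak, while any pair of retained significant genes has a positive count,
    the involved gene with the lowest maximum PP(H4) is excluded (ties
    excluded lexicographically-larger gene id first).  Genes in peaks with
    fewer than two significant genes are never touched.  Returns the
    filtered matrix and a report of exclusions.
    """
    m = _check_matrix(matrix)
    cm: dict[frozenset, float] = {}
    for e in crossmap:
        key = frozenset((e.gene_a, e.gene_b))
        cm[key] = max(cm.get(key, 0.0), e.count)

    excluded: list[dict] = []
    keep = pd.Series(True, index=m.index)
    for pid, grp in m.groupby("peak_id"):
        sig = grp[grp["significant"]]
        genes = set(sig["gene_id"].unique())
        if len(genes) < 2:
            continue
        max_pp = sig.groupby("gene_id")["pp_h4"].max()
        retained = set(genes)
        while True:
            conflicted = {
                g
                for g in retained
                for h in retained
                if g != h and cm.get(frozenset((g, h)), 0.0) > 0
            }
            if not conflicted:
                break
            victim = min(conflicted, key=lambda g: (max_pp[g], tuple(-ord(c) for c in g)))
            retained.discard(victim)
            excluded.append({"peak_id": pid, "gene_id": victim, "max_pp_h4": float(max_pp[victim])})
            keep &= ~((m["peak_id"] == pid) & (m["gene_id"] == victim))
    return m[keep].reset_index(drop=True), pd.DataFrame(
        excluded, columns=["peak_id", "gene_id", "max_pp_h4"]
    )


def build_control_pairs(
    matrix: pd.DataFrame, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched case/control gene pairs for the co-regulation contrast.

    Per (peak, gene) the test with the highest PP(H4) is pre-selected.  For
    every unordered pair of significant genes at a peak (a case pair), one
    member is picked at random and paired with a non-significant gene tested
    at the same peak and expressed in the cell type of the *non-selected*
    member; each non-significant gene serves as a control at most once.
    Case pairs lacking an eligible control are dropped and reported, so the
    retained case and control counts are equal.
    """
    m = _check_matrix(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    top = (
        m.sort_values(["pp_h4", "study_id"], ascending=[False, True])
        .groupby(["peak_id", "gene_id"], as_index=False)
        .first()
    )
    used_controls: set[tuple[str, str]] = set()
    pairs, dropped = [], []
    for pid in sorted(top["peak_id"].unique()):
        grp = top[top["peak_id"] == pid]
        sig = grp[grp["significant"]].sort_values("gene_id")
        nonsig = grp[~grp["significant"].astype(bool)]
        genes = list(sig["gene_id"])
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                pick_a = bool(rng.integers(2))
                selected, nonselected = (a, b) if pick_a else (b, a)
                ct = sig[sig["gene_id"] == nonselected]["cell_type"].iloc[0]
                elig = nonsig[
                    (nonsig["cell_type"] == ct)
                    & ~nonsig["gene_id"].map(lambda g: (pid, g) in used_controls)
                ].sort_values("gene_id")
                if len(elig) == 0:
                    dropped.append({"peak_id": pid, "gene_a": a, "gene_b": b, "reason": "no eligible control"})
                    continue
                ctrl = elig.iloc[int(rng.integers(len(elig)))]
                used_controls.add((pid, ctrl["gene_id"]))
                pairs.append(
                    {
                        "peak_id": pid,
                        "case_gene_a": a,
                        "case_gene_b": b,
                        "case_cell_type_a": sig[sig["gene_id"] == a]["cell_type"].iloc[0],
                        "case_cell_type_b": sig[sig["gene_id"] == b]["cell_type"].iloc[0],
                        "control_gene_a": selected,
                        "control_gene_b": ctrl["gene_id"],
                        "control_cell_type": ct,
                    }
                )
    return pd.DataFrame(pairs), pd.DataFrame(dropped, columns=["peak_id", "gene_a", "gene_b", "reason"])


def _pair_r2(expr: Mapping[str, pd.DataFrame], cell_type: str, g1: str, g2: str) -> float | None:
    if cell_type not in expr:
        return None
    mat = expr[cell_type]
    if g1 not in mat.index or g2 not in mat.index:
        return None
    x = np.log1p(mat.loc[g1].values.astype(float))
    y = np.log1p(mat.loc[g2].values.astype(float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def coregulation_contrasts(
    pairs: pd.DataFrame,
    expression: Mapping[str, pd.DataFrame],
    tss: Mapping[str, tuple[str, int]],
) -> dict:
    """Case vs control contrasts of expression correlation and TSS distance.

    For each pair the squared Pearson correlation of log(x+1) expression is
    computed in the pair's cell type (case pairs: the cell type of each
    member's best test; the correlation uses the first member's cell type
    when they differ, since expression matrices are per cell type).  Linear
    models of r² and of TSS distance on the case indicator use peak-clustered
    sandwich standard errors.  Pairs with missing or constant expression are
    dropped and counted.
    """
    rows, n_dropped = [], 0
    for _, p in pairs.iterrows():
        for is_case, (g1, g2, ct) in (
            (1, (p["case_gene_a"], p["case_gene_b"], p["case_cell_type_a"])),
            (0, (p["control_gene_a"], p["control_gene_b"], p["control_cell_type"])),
        ):
            r2 = _pair_r2(expression, ct, g1, g2)
            if r2 is None:
                n_dropped += 1
                continue
            d = None
            if g1 in tss and g2 in tss and tss[g1][0] == tss[g2][0]:
                d = abs(int(tss[g1][1]) - int(tss[g2][1]))
            rows.append({"peak_id": p["peak_id"], "case": is_case, "r2": r2, "dist": d})
    df = pd.DataFrame(rows)
    if df.empty or df["case"].nunique() < 2:
        raise ValueError("not enough case/control pairs with expression data")

    def _clustered_lm(y: pd.Series, sub: pd.DataFrame) -> tuple[float, float]:
        X = sm.add_constant(sub["case"].astype(float))
        res = sm.OLS(y.astype(float), X).fit(
            cov_type="cluster", cov_kwds={"groups": np.asarray(sub["peak_id"])}
        )
        return float(res.params["case"]), float(res.pvalues["case"])

    delta_r2, p_r2 = _clustered_lm(df["r2"], df)
    dd = df.dropna(subset=["dist"])
    if len(dd) and dd["case"].nunique() == 2:
        delta_dist, p_dist = _clustered_lm(dd["dist"], dd)
    else:
        delta_dist, p_dist = np.nan, np.nan
    return {
        "delta_r2": delta_r2,
        "p_r2": p_r2,
        "delta_dist": delta_dist,
        "p_dist": p_dist,
        "n_pairs": int(df["case"].sum()),
        "n_dropped": n_dropped,
        "table": df,
    }


def same_celltype_pair_enrichment(
    matrix: pd.DataFrame,
    peak_positions: Mapping[str, int] | None = None,
    dedup_dist: int = 30_000,
    exclude_cell_types: Sequence[str] = ("whole blood",),
    seed: int | np.random.Generator = 0,
) -> dict:
    """Do within-peak test pairs co-colocalise more in the same cell type?

    Whole-blood tests are excluded; when ``peak_positions`` is given, peaks
    whose top fine-mapped positions lie within ``dedup_dist`` are de-duplicated
    by seeded random retention.  Over all within-peak pairs of tests on
    distinct genes, a logistic model of both-significant on a same-cell-type
    indicator is fitted with peak-clustered sandwich errors.
    """
    m = _check_matrix(matrix)
    m = m[~m["cell_type"].isin(exclude_cell_types)].copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if peak_positions:
        kept_peaks = _dedup_peaks(sorted(set(m["peak_id"]) & set(peak_positions)), peak_positions, dedup_dist, rng)
        m = m[m["peak_id"].isin(kept_peaks)]
    rows = []
    for pid, grp in m.groupby("peak_id"):
        recs = grp.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if recs[i]["gene_id"] == recs[j]["gene_id"]:
                    continue
                rows.append(
                    {
                        "peak_id": pid,
                        "both_significant": int(bool(recs[i]["significant"]) and bool(recs[j]["significant"])),
                        "same_cell_type": int(recs[i]["cell_type"] == recs[j]["cell_type"]),
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no within-peak gene pairs")
    if df["same_cell_type"].nunique() < 2:
        warnings.warn("same-cell-type indicator constant; term dropped", UserWarning)
        return {"log_or": np.nan, "odds_ratio": np.nan, "p": np.nan, "n_pairs": len(df)}
    ests = fit_cluster_logistic(df, "both_significant", ["same_cell_type"], "peak_id")
    e = ests[0]
    return {
        "log_or": e.log_or,
        "odds_ratio": float(np.exp(e.log_or)),
        "p": e.pvalue,
        "n_pairs": len(df),
        "unreliable": e.unreliable,
    }


def _dedup_peaks(peak_ids, positions, dist, rng) -> set:
    order = sorted(peak_ids, key=lambda p: positions[p])
    kept: set = set()
    cluster: list = []
    out: list[list] = []
    for p in order:
        if cluster and positions[p] - positions[cluster[-1]] >= dist:
            out.append(cluster)
            cluster = []
        cluster.append(p)
    if cluster:
        out.append(cluster)
    for cl in out:
        kept.add(cl[int(rng.integers(len(cl)))])
    return kept


def lead_snp_r2(
    haplotypes: np.ndarray, idx_pairs: Sequence[tuple[int, int]]
) -> list[float | None]:
    """Squared allele-count correlation for each variant index pair.

    ``haplotypes`` is a (haplotype x variant) 0/1 matrix.  Monomorphic
    variants yield None (undefined correlation)."""
    out: list[float | None] = []
    H = np.asarray(haplotypes, dtype=float)
    for i, j in idx_pairs:
        a, b = H[:, i], H[:, j]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out.append(None)
            continue
        out.append(float(np.corrcoef(a, b)[0, 1] ** 2))
    return out


def enhancer_link_rates(
    peaks_leads: Mapping[str, tuple[str, int]],
    matrix: pd.DataFrame,
    links: Sequence[EnhancerLink],
    score_min: float = 0.164,
    max_strata: int = 3,
) -> dict:
    """Are peak-lead enhancers linked to the colocalising eGenes?

    Links with score > ``score_min`` are active.  Analysis is restricted to
    peaks whose lead (1-based) falls inside >= 1 active enhancer interval
    (0-based half-open).  Per (peak, gene, cell type) the max-PP(H4) test is
    kept; the outcome is whether an enhancer overlapping the lead is linked
    to that gene in the test's cell type.  Proportions are reported per
    (number-of-significant-genes stratum x significance) cell, the stratum
    top-coded at ``max_strata``; a random-intercept (peak) logistic model
    with significance, stratum and their interaction as fixed effects is
    fitted variationally.
    """
    m = _check_matrix(matrix)
    active = [l for l in links if l.score > score_min]
    if not active:
        warnings.warn("no active enhancer links at this score threshold", UserWarning)
        return {"table": pd.DataFrame(), "model": None, "n_peaks": 0}

    by_ct: dict[str, list[EnhancerLink]] = {}
    for l in active:
        by_ct.setdefault(l.cell_type, []).append(l)

    def overlapping(chrom: str, pos: int) -> list[EnhancerLink]:
        z = pos - 1
        return [l for l in active if l.chrom == chrom and l.start <= z < l.end]

    peak_hits = {
        pid: overlapping(chrom, pos)
        for pid, (chrom, pos) in peaks_leads.items()
        if overlapping(chrom, pos)
    }
    if not peak_hits:
        warnings.warn("no peak lead overlaps an active enhancer", UserWarning)
        return {"table": pd.DataFrame(), "model": None, "n_peaks": 0}

    sub = m[m["peak_id"].isin(peak_hits)].copy()
    sub = (
        sub.sort_values("pp_h4", ascending=False)
        .groupby(["peak_id", "gene_id", "cell_type"], as_index=False)
        .first()
    )
    n_sig = (
        sub[sub["significant"]].groupby("peak_id")["gene_id"].nunique()
        .reindex(sub["peak_id"].unique(), fill_value=0)
    )
    rows = []
    for _, t in sub.iterrows():
        hits = peak_hits[t["peak_id"]]
        linked = any(l.gene_id == t["gene_id"] and l.cell_type == t["cell_type"] for l in hits)
        rows.append(
            {
                "peak_id": t["peak_id"],
                "gene_id": t["gene_id"],
                "cell_type": t["cell_type"],
                "significant": int(bool(t["significant"])),
                "n_sig_genes": int(min(n_sig[t["peak_id"]], max_strata)),
                "linked": int(linked),
            }
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["n_sig_genes", "significant"])["linked"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "proportion_linked", "count": "n_tests"})
    )
    model = _fit_peak_glmm(df)
    return {"table": table, "data": df, "model": model, "n_peaks": len(peak_hits)}


def _fit_peak_glmm(df: pd.DataFrame) -> dict | None:
    if df["linked"].nunique() < 2 or df["significant"].nunique() < 2:
        warnings.warn("degenerate outcome/predictor for GLMM; model skipped", UserWarning)
        return None
    work = df.copy()
    work["sig_x_nsig"] = work["significant"] * work["n_sig_genes"]
    fixed = ["significant", "n_sig_genes", "sig_x_nsig"]
    fixed = [c for c in fixed if work[c].nunique() > 1]
    exog = sm.add_constant(work[fixed].astype(float))
    peaks = pd.Categorical(work["peak_id"])
    exog_vc = pd.get_dummies(peaks).values.astype(float)
    ident = np.zeros(exog_vc.shape[1], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glmm = BinomialBayesMixedGLM(
            work["linked"].values.astype(float), exog.values, exog_vc, ident
        )
        fit = glmm.fit_vb()
    k = exog.shape[1]
    names = list(exog.columns)
    means = fit.fe_mean[:k]
    sds = fit.fe_sd[:k]
    return {
        "terms": names,
        "coef": dict(zip(names, map(float, means))),
        "sd": dict(zip(names, map(float, sds))),
        "z": dict(zip(names, map(float, means / sds))),
    }
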