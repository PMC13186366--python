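"""Five-hypothesis Bayesian colocalisation, test orchestration and FDR calibration.

For two traits measured in one genomic region, the single-causal-variant
colocalisation model weighs five hypotheses: H0 neither trait associated,
H1/H2 only one trait associated, H3 both associated through distinct causal
variants, H4 both share one causal variant.  Per-variant Wakefield log ABFs
for each trait combine into hypothesis-level evidence through log-sum-exp
identities, with priors p1, p2 (variant causal for one trait) and p12
(causal for both).  The significance threshold alpha on PP(H4) is calibrated
from the tests themselves: the estimated FDR among tests with PP(H4) > alpha
is mean(1 - PP(H4)) over that set, and alpha is the smallest observed value
bringing it under the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import (
    CoverageQC,
    FinemapResult,
    coverage_qc,
    default_prior_sd,
    finemap_posteriors,
    wakefield_log_abf,
)
from .sumstats import EGene, NoOverlapError, SumStatsTable, VariantKey, harmonise_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ColocPriors",
    "ColocResult",
    "FdrCalibration",
    "coloc_abf",
    "run_region_tests",
    "fdr_threshold",
    "call_significant",
    "results_to_frame",
]

HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality.

    p12 defaults to the conservative 5e-6; p1 = p2 = 1e-4 follow the
    single-causal-variant framework's convention.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-6

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= min(p1, p2) < 1")


@dataclass
class ColocResult:
    """Posterior vector and QC for one (GWAS, eGene, eQTL-study) test."""

    gwas_id: str
    study_id: str
    gene_id: str
    pp: np.ndarray  # PP(H0..H4)
    n_shared: int
    qc: CoverageQC
    lead_gwas: VariantKey
    lead_eqtl: VariantKey
    region: tuple[str, int] = ("NA", -1)  # (chrom, gene TSS)
    significant: bool | None = None
    # optional per-shared-variant detail used by peak assignment
    shared_variants: list[VariantKey] | None = None
    post_gwas_shared: np.ndarray | None = None
    labf_sum_shared: np.ndarray | None = None

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); -inf when a <= b (within a fp guard)."""
    if a <= b + 1e-12:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(labf1, labf2, priors: ColocPriors = ColocPriors()) -> np.ndarray:
    """Posterior probabilities of H0..H4 from aligned per-variant log ABFs.

    With S1 = logsumexp(labf1), S2 = logsumexp(labf2) and
    S12 = logsumexp(labf1 + labf2):

        lH0 = 0
        lH1 = log p1 + S1
        lH2 = log p2 + S2
        lH3 = log p1 + log p2 + log(exp(S1 + S2) - exp(S12))
        lH4 = log p12 + S12

    and pp = softmax(lH0..lH4).  The H3 sum runs over ordered pairs of
    distinct variants, hence the subtraction; with a single shared variant
    PP(H3) is a structural zero.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or l1.size < 1:
        raise ValueError("labf1 and labf2 must be equal-length 1-D arrays")
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lh = np.array(
        [
            0.0,
            np.log(priors.p1) + s1,
            np.log(priors.p2) + s2,
            np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(s1 + s2, s12),
            np.log(priors.p12) + s12,
        ]
    )
    return np.exp(lh - logsumexp(lh))


def fdr_threshold(pph4s, target: float = 0.05) -> "FdrCalibration":
    """Calibrate the PP(H4) significance threshold to an FDR target.

    Candidate thresholds are the observed unique PP(H4) values (the
    estimated FDR is a step function changing only there).  For each
    candidate alpha, est_fdr = mean(1 - PP(H4)) over tests with
    PP(H4) > alpha; when no test strictly exceeds alpha the closed set
    PP(H4) >= alpha is used instead.  alpha is the smallest candidate with
    est_fdr < target; if none qualifies the result is uncalibratable
    (alpha is None).
    """
    pp = np.asarray(pph4s, dtype=float)
    if pp.size == 0:
        raise ValueError("no PP(H4) values supplied")
    if np.any((pp < 0) | (pp > 1)):
        raise ValueError("PP(H4) values must lie in [0, 1]")
    cands = np.unique(pp)
    curve = []
    for a in cands:
        above = pp[pp > a]
        if above.size == 0:
            above = pp[pp >= a]
        curve.append((float(a), float(np.mean(1.0 - above))))
    for a, fdr in curve:
        if fdr < target:
            return FdrCalibration(alpha=a, est_fdr_at_alpha=fdr, curve=curve, target=target)
    return FdrCalibration(alpha=None, est_fdr_at_alpha=None, curve=curve, target=target)


@dataclass
class FdrCalibration:
    """PP(H4) threshold and the estimated-FDR curve behind it."""

    alpha: float | None
    est_fdr_at_alpha: float | None
    curve: list[tuple[float, float]] = field(default_factory=list)
    target: float = 0.05

    @property
    def calibrated(self) -> bool:
        return self.alpha is not None

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["threshold", "est_fdr"])


def call_significant(
    results: Sequence[ColocResult], calibration: FdrCalibration | float
) -> list[ColocResult]:
    """Annotate results with significance: PP(H4) > alpha (strict).

    ``calibration`` may be an :class:`FdrCalibration` or a raw alpha.  An
    uncalibratable calibration marks everything non-significant.
    """
    if isinstance(calibration, FdrCalibration):
        alpha = calibration.alpha
    else:
        alpha = float(calibration)
    for r in results:
        r.significant = bool(alpha is not None and r.pp_h4 > alpha)
    return list(results)


def run_region_tests(
    gwas: SumStatsTable,
    eqtl_panel: Mapping[str, Mapping[str, SumStatsTable]],
    egenes: Sequence[EGene],
    window_half: int = 1_000_000,
    gwas_sig: float = 5e-8,
    qc_threshold: float = 0.9,
    priors: ColocPriors = ColocPriors(),
    gene_blocklist: Sequence[str] = (),
) -> tuple[list[ColocResult], pd.DataFrame]:
    """Run colocalisation for every (eQTL study, eGene) against one GWAS.

    For each test the two datasets are restricted to the window
    [TSS - window_half, TSS + window_half]; the test runs only if the GWAS
    has at least one variant with p < ``gwas_sig`` there.  Both full
    regional variant sets are fine-mapped, the cross-trait coverage QC is
    computed on the harmonised shared set, and coloc runs on the shared set
    only when min(q1, q2) > ``qc_threshold``.  Skips are data, not errors:
    the second return value logs every skipped test and its reason.
    """
    results: list[ColocResult] = []
    skips: list[dict] = []

    def skip(study, gene, reason):
        skips.append({"gwas_id": gwas.study_id, "study_id": study, "gene_id": gene, "reason": reason})

    blocked = set(gene_blocklist)
    for eg in egenes:
        if eg.gene_id in blocked:
            skip(eg.study_id, eg.gene_id, "gene blocklisted")
            continue
        per_gene = eqtl_panel.get(eg.study_id, {})
        if eg.gene_id not in per_gene:
            skip(eg.study_id, eg.gene_id, "no eQTL summary statistics")
            continue
        chrom, tss, _ = eg.tss
        lo, hi = tss - window_half, tss + window_half
        gsub = gwas.data[
            (gwas.data["chrom"] == chrom) & (gwas.data["pos"] >= lo) & (gwas.data["pos"] <= hi)
        ]
        if len(gsub) == 0:
            skip(eg.study_id, eg.gene_id, "no GWAS variants in window")
            continue
        if float(gsub["pvalue"].min()) >= gwas_sig:
            skip(eg.study_id, eg.gene_id, "no genome-wide-significant variant")
            continue
        esub = per_gene[eg.gene_id].data
        esub = esub[(esub["chrom"] == chrom) & (esub["pos"] >= lo) & (esub["pos"] <= hi)]
        if len(esub) == 0:
            skip(eg.study_id, eg.gene_id, "no eQTL variants in window")
            continue
        t_gwas = SumStatsTable(gwas.study_id, gwas.trait_type, gsub.reset_index(drop=True))
        t_eqtl = SumStatsTable(
            per_gene[eg.gene_id].study_id, per_gene[eg.gene_id].trait_type, esub.reset_index(drop=True)
        )
        try:
            a2, b2, shared, _rep = harmonise_pair(t_gwas, t_eqtl)
        except NoOverlapError:
            skip(eg.study_id, eg.gene_id, "no shared variants")
            continue
        # fine-map each trait on its FULL regional variant set
        fm1 = finemap_posteriors(
            wakefield_log_abf(
                t_gwas.data["beta"], t_gwas.data["se"], default_prior_sd(t_gwas.trait_type)
            ),
            t_gwas.variants,
        )
        fm2 = finemap_posteriors(
            wakefield_log_abf(
                t_eqtl.data["beta"], t_eqtl.data["se"], default_prior_sd(t_eqtl.trait_type)
            ),
            t_eqtl.variants,
        )
        # coverage over the shared set in each trait's own orientation:
        # posterior mass is allele-orientation invariant, match on position
        pos_shared = {(v.chrom, v.pos) for v in shared}
        q1 = float(
            sum(p for v, p in zip(fm1.variants, fm1.posterior) if (v.chrom, v.pos) in pos_shared)
        )
        q2 = float(
            sum(p for v, p in zip(fm2.variants, fm2.posterior) if (v.chrom, v.pos) in pos_shared)
        )
        qc = CoverageQC(min(q1, 1.0), min(q2, 1.0), min(q1, q2) > qc_threshold, qc_threshold)
        if not qc.pass_:
            skip(eg.study_id, eg.gene_id, "coverage QC fail")
            continue
        labf1 = wakefield_log_abf(a2.data["beta"], a2.data["se"], default_prior_sd(a2.trait_type))
        labf2 = wakefield_log_abf(b2.data["beta"], b2.data["se"], default_prior_sd(b2.trait_type))
        pp = coloc_abf(labf1, labf2, priors)
        post1 = np.exp(labf1 - logsumexp(labf1))
        lead_g = shared[int(np.argmax(labf1))]
        lead_e = shared[int(np.argmax(labf2))]
        results.append(
            ColocResult(
                gwas_id=gwas.study_id,
                study_id=eg.study_id,
                gene_id=eg.gene_id,
                pp=pp,
                n_shared=len(shared),
                qc=qc,
                lead_gwas=lead_g,
                lead_eqtl=lead_e,
                region=(chrom, tss),
                shared_variants=shared,
                post_gwas_shared=post1,
                labf_sum_shared=np.asarray(labf1) + np.asarray(labf2),
            )
        )
    skip_log = pd.DataFrame(skips, columns=["gwas_id", "study_id", "gene_id", "reason"])
    return results, skip_log


def results_to_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    """Flatten results to the summary-table shape (one row per test)."""
    rows = []
    for r in results:
        row = {
            "gwas_id": r.gwas_id,
            "study_id": r.study_id,
            "gene_id": r.gene_id,
            "nsnps": r.n_shared,
        }
        row.update({h: float(p) for h, p in zip(HYPOTHESES, r.pp)})
        row.update(
            {
                "q1": r.qc.q1,
                "q2": r.qc.q2,
                "lead_gwas": f"{r.lead_gwas.chrom}:{r.lead_gwas.pos}:{r.lead_gwas.ref}:{r.lead_gwas.alt}",
                "lead_eqtl": f"{r.lead_eqtl.chrom}:{r.lead_eqtl.pos}:{r.lead_eqtl.ref}:{r.lead_eqtl.alt}",
                "significant": r.significant,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
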