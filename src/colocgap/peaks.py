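"""Independent GWAS peaks: merging credible-set leads and assigning coloc tests.

A peak is an independent GWAS signal represented by a fine-mapping
credible-set lead variant.  Leads closer than a merge distance (default
30 kb) on the same trait and chromosome are chained into one peak whose
representative lead is the smallest-p member.  Colocalisation tests are
assigned to the peak(s) whose lead falls in the test's regional window;
significant tests with several candidate peaks are resolved deterministically
by the GWAS fine-mapping posterior mass at the candidate leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .coloc import ColocResult
from .sumstats import VariantKey

__all__ = [
    "Peak",
    "PeakAssignment",
    "define_peaks",
    "assign_tests_to_peaks",
    "peak_coloc_rate",
]


@dataclass
class Peak:
    trait_id: str
    lead: VariantKey
    lead_p: float
    merged_leads: list[VariantKey] = field(default_factory=list)
    peak_id: str = ""


@dataclass
class PeakAssignment:
    test_ref: tuple[str, str, str]  # (gwas_id, study_id, gene_id)
    peak_ids: list[str]


def define_peaks(
    leads: Sequence[tuple[str, VariantKey, float]], merge_dist: int = 30_000
) -> list[Peak]:
    """Single-linkage merge of credible-set leads into independent peaks.

    Per trait and chromosome, leads with pairwise distance strictly below
    ``merge_dist`` chain into one peak; the representative lead is the
    smallest-p member (position tie-break).  Deterministic and invariant to
    input order.
    """
    df = pd.DataFrame(
        {
            "trait": [t for t, _, _ in leads],
            "chrom": [v.chrom for _, v, _ in leads],
            "pos": [v.pos for _, v, _ in leads],
            "key": [v for _, v, _ in leads],
            "p": [p for _, _, p in leads],
        }
    )
    peaks: list[Peak] = []
    for (trait, chrom), grp in df.groupby(["trait", "chrom"], sort=True):
        grp = grp.sort_values(["pos", "p"]).reset_index(drop=True)
        gaps = grp["pos"].diff()
        chain_id = (gaps >= merge_dist).cumsum()
        for _, chain in grp.groupby(chain_id):
            best = chain.sort_values(["p", "pos"]).iloc[0]
            peaks.append(
                Peak(
                    trait_id=trait,
                    lead=best["key"],
                    lead_p=float(best["p"]),
                    merged_leads=[k for k in chain["key"] if k != best["key"]],
                )
            )
    peaks.sort(key=lambda p: (p.trait_id, p.lead.chrom, p.lead.pos))
    for i, p in enumerate(peaks):
        p.peak_id = f"{p.trait_id}__peak{i:04d}"
    return peaks


def assign_tests_to_peaks(
    tests: Sequence[ColocResult],
    peaks: Sequence[Peak],
    window_half: int = 1_000_000,
) -> list[PeakAssignment]:
    """Assign each colocalisation test to GWAS peak(s) in its window.

    Candidates are peaks of the test's GWAS whose lead lies within
    window_half of the test's gene TSS.  One candidate: assigned.  Several
    candidates and a significant test: assigned to the peak whose lead
    carries the largest GWAS fine-map posterior within the shared variant
    set (fallback: the peak lead nearest the shared variant maximising
    labf1 + labf2).  Several candidates and a non-significant test: assigned
    to all (coloc rejected all of them equally).  No candidate: an empty
    assignment, recorded.
    """
    by_trait: dict[str, list[Peak]] = {}
    for p in peaks:
        by_trait.setdefault(p.trait_id, []).append(p)

    out: list[PeakAssignment] = []
    for t in tests:
        chrom, tss = t.region
        cands = [
            p
            for p in by_trait.get(t.gwas_id, [])
            if p.lead.chrom == chrom and abs(p.lead.pos - tss) <= window_half
        ]
        ref = (t.gwas_id, t.study_id, t.gene_id)
        if len(cands) <= 1:
            out.append(PeakAssignment(ref, [p.peak_id for p in cands]))
            continue
        if not t.significant:
            out.append(PeakAssignment(ref, [p.peak_id for p in cands]))
            continue
        chosen = _resolve_multi_peak(t, cands)
        out.append(PeakAssignment(ref, [chosen.peak_id]))
    return out


def _resolve_multi_peak(t: ColocResult, cands: list[Peak]) -> Peak:
    if t.shared_variants is not None and t.post_gwas_shared is not None:
        pos_index = {(v.chrom, v.pos): i for i, v in enumerate(t.shared_variants)}
        masses = []
        for p in cands:
            i = pos_index.get((p.lead.chrom, p.lead.pos))
            masses.append(float(t.post_gwas_shared[i]) if i is not None else -1.0)
        if max(masses) > 0:
            return cands[int(np.argmax(masses))]
        if t.labf_sum_shared is not None:
            # fallback: nearest peak lead to the jointly most-supported variant
            j = int(np.argmax(t.labf_sum_shared))
            anchor = t.shared_variants[j].pos
            return min(cands, key=lambda p: (abs(p.lead.pos - anchor), p.lead.pos))
    return min(cands, key=lambda p: (abs(p.lead.pos - t.region[1]), p.lead.pos))


def peak_coloc_rate(
    assignments: Sequence[PeakAssignment],
    flags: dict[tuple[str, str, str], bool],
    peaks: Sequence[Peak],
) -> tuple[float, float, float, pd.DataFrame]:
    """Proportion of assessable peaks with >= 1 significant assigned test.

    A peak is assessable if at least one test was assigned to it.  Returns
    the proportion with a 95% Wilson score interval and a per-trait table.
    """
    assigned: dict[str, bool] = {}
    for a in assignments:
        sig = bool(flags.get(a.test_ref, False))
        for pid in a.peak_ids:
            assigned[pid] = assigned.get(pid, False) or sig
    if not assigned:
        raise ValueError("no peaks have any assigned test")
    trait_of = {p.peak_id: p.trait_id for p in peaks}
    rows = []
    for pid, sig in assigned.items():
        rows.append({"peak_id": pid, "trait_id": trait_of.get(pid, "NA"), "colocalised": sig})
    df = pd.DataFrame(rows)
    k, n = int(df["colocalised"].sum()), len(df)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    per_trait = (
        df.groupby("trait_id")["colocalised"].agg(["sum", "count", "mean"]).reset_index()
        .rename(columns={"sum": "n_coloc", "count": "n_peaks", "mean": "proportion"})
    )
    return k / n, float(lo), float(hi), per_trait
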