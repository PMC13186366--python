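"""Synthetic GWAS/eQTL inputs with exported ground truth.

Every analysis in the package can be exercised without external downloads:
this module fabricates LD-structured haplotype panels, paired summary
statistics generated under each colocalisation hypothesis H0-H4, a
multi-study panel (study metadata, per-study per-gene eQTL summary
statistics, credible-set leads, gene annotation, expression matrices with
co-regulated pairs sharing a latent factor, enhancer-gene links and
cross-mappability tables), and an evaluation harness comparing calls to the
generative truth.

All randomness flows from one integer seed through numpy SeedSequence
spawning, so module-level reruns are reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .multicoloc import CrossmapEntry, EnhancerLink
from .sumstats import StudyMeta, SumStatsTable, VariantKey

__all__ = [
    "LDPanel",
    "SyntheticTruth",
    "PanelConfig",
    "SyntheticBundle",
    "simulate_ld_panel",
    "simulate_region_pair",
    "simulate_study_panel",
    "simulate_test_flags",
    "truth_report",
]


def _vstr(v: VariantKey) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class LDPanel:
    """Binary haplotype panel with distance-decaying linkage disequilibrium."""

    haplotypes: np.ndarray  # (n_haplotypes, n_variants) in {0,1}
    variants: list[VariantKey]
    freqs: np.ndarray  # empirical alt-allele frequencies

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even")

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def r2(self, i: int, j: int) -> float:
        a = self.haplotypes[:, i].astype(float)
        b = self.haplotypes[:, j].astype(float)
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    def sample_genotypes(self, n: int, rng) -> np.ndarray:
        """Diploid genotypes: sums of two haplotypes drawn with replacement."""
        rng = _rng(rng)
        h = self.haplotypes
        return (
            h[rng.integers(h.shape[0], size=n)] + h[rng.integers(h.shape[0], size=n)]
        ).astype(float)


@dataclass
class SyntheticTruth:
    """Generative ground truth for one region or a whole panel."""

    hypothesis: dict = field(default_factory=dict)  # region_id -> H0..H4
    causal_gwas: dict = field(default_factory=dict)  # region_id -> variant str
    causal_eqtl: dict = field(default_factory=dict)  # (region, study, gene) or region -> variant str
    test_hypothesis: dict = field(default_factory=dict)  # (gwas, study, gene) -> H label
    coregulated_pairs: list = field(default_factory=list)  # [(gene_a, gene_b), ...]
    enrichment_multipliers: dict = field(default_factory=dict)  # cell_type -> multiplier
    trait_sd: float = 1.0
    causal_maf: dict = field(default_factory=dict)  # region_id -> MAF of GWAS causal
    study_n: dict = field(default_factory=dict)  # study_id -> eQTL sample size
    link_probs: tuple = (0.4, 0.03)


def simulate_ld_panel(
    n_variants: int,
    n_haplotypes: int,
    decay: float,
    region_span: int,
    seed,
    chrom: str = "1",
    start: int = 1_000_000,
    maf_bounds: tuple[float, float] = (0.01, 0.5),
) -> LDPanel:
    """Haplotype panel from a first-order Gaussian dependence chain.

    A latent AR(1) process with per-step autocorrelation decay**(distance
    in kb) is thresholded at each variant's target allele frequency, giving
    r² that decays with physical distance; decay=0 gives independent
    variants.  Positions are uniform over ``region_span``; target alt-allele
    frequencies are uniform within ``maf_bounds``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0 <= decay < 1):
        raise ValueError("decay must lie in [0, 1)")
    rng = _rng(seed)
    if n_haplotypes % 2:
        n_haplotypes += 1
    pos = np.sort(rng.choice(np.arange(region_span), size=n_variants, replace=False)) + start
    f = rng.uniform(maf_bounds[0], maf_bounds[1], size=n_variants)
    z = np.empty((n_haplotypes, n_variants))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    for j in range(1, n_variants):
        a = decay ** ((pos[j] - pos[j - 1]) / 1000.0) if decay > 0 else 0.0
        z[:, j] = a * z[:, j - 1] + np.sqrt(1 - a**2) * rng.standard_normal(n_haplotypes)
    hap = (z < stats.norm.ppf(f)).astype(np.uint8)
    # guard against monomorphic columns (possible at extreme frequencies)
    for j in range(n_variants):
        s = hap[:, j].sum()
        if s == 0:
            hap[rng.integers(n_haplotypes), j] = 1
        elif s == n_haplotypes:
            hap[rng.integers(n_haplotypes), j] = 0
    freqs = hap.mean(axis=0)
    alleles = rng.choice(["A", "C", "G", "T"], size=(n_variants, 2))
    variants = []
    for j in range(n_variants):
        ref, alt = alleles[j]
        if ref == alt:
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        variants.append(VariantKey(chrom, int(pos[j]), ref, alt))
    return LDPanel(hap, variants, freqs)


def _marginal_ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression (vectorised closed form)."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = (gc**2).sum(axis=0)
    sgg = np.where(sgg == 0, np.nan, sgg)
    beta = gc.T @ yc / sgg
    syy = float((yc**2).sum())
    ss_res = syy - beta**2 * sgg
    sigma2 = np.maximum(ss_res, 1e-300) / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, np.clip(p, 1e-300, 1.0)


def _marginal_allelic(
    G: np.ndarray, case: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant allelic log odds ratio from 2x2 allele-count tables."""
    n_case = int(case.sum())
    n_ctl = len(case) - n_case
    a = G[case].sum(axis=0) + 0.5
    b = 2 * n_case - G[case].sum(axis=0) + 0.5
    c = G[~case].sum(axis=0) + 0.5
    d = 2 * n_ctl - G[~case].sum(axis=0) + 0.5
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, 1e-300, 1.0)


def _sumstats_from_panel(
    panel: LDPanel,
    G: np.ndarray,
    y,
    study_id: str,
    trait_type: str,
    n: int,
) -> SumStatsTable:
    if trait_type == "case-control":
        beta, se, p = _marginal_allelic(G, y)
    else:
        beta, se, p = _marginal_ols(G, np.asarray(y, dtype=float))
    maf = np.minimum(panel.freqs, 1 - panel.freqs)
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            "ref": [v.ref for v in panel.variants],
            "alt": [v.alt for v in panel.variants],
            "beta": beta,
            "se": se,
            "pvalue": p,
            "maf": np.clip(maf, 1e-6, 0.5),
            "n": n,
        }
    )
    return SumStatsTable(study_id, trait_type, df)


def _pick_low_ld_partner(panel: LDPanel, idx: int, rng, max_r2: float = 0.05) -> int:
    order = rng.permutation(len(panel.variants))
    for j in order:
        if j != idx and panel.r2(idx, int(j)) < max_r2:
            return int(j)
    return int(order[0]) if order[0] != idx else int(order[1])


def simulate_region_pair(
    panel: LDPanel,
    scenario: str,
    n1: int,
    n2: int,
    beta1: float,
    beta2: float,
    trait_types: tuple[str, str] = ("quantitative", "quantitative"),
    seed=0,
    causal_idx: int | None = None,
    trait_sd: float = 1.0,
    prevalence: float = 0.1,
    h3_max_r2: float = 0.05,
    study_ids: tuple[str, str] = ("gwas", "eqtl"),
    region_id: str = "region",
) -> tuple[SumStatsTable, SumStatsTable, SyntheticTruth]:
    """Paired summary statistics under one colocalisation hypothesis.

    Phenotypes are genotype.beta plus Gaussian noise of SD ``trait_sd``
    (case-control traits via a liability threshold at the given prevalence);
    per-variant marginal regressions give beta/se/p, as emitted by real
    GWAS/eQTL pipelines.  H4 shares one causal variant; H3 draws a second
    causal with r² < ``h3_max_r2`` to the first; H1/H2 leave the other trait
    null; H0 leaves both null.
    """
    if scenario not in {"H0", "H1", "H2", "H3", "H4"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = _rng(seed)
    m = len(panel.variants)
    if causal_idx is None:
        # favour a well-powered (common, central) causal variant
        mid = np.arange(m // 4, max(m // 4 + 1, 3 * m // 4))
        causal_idx = int(mid[np.argmax(panel.freqs[mid] * (1 - panel.freqs[mid]))])
    c1 = causal_idx if scenario in {"H1", "H3", "H4"} else None
    if scenario == "H4":
        c2 = causal_idx
    elif scenario == "H3":
        c2 = _pick_low_ld_partner(panel, causal_idx, rng, h3_max_r2)
    elif scenario == "H2":
        c2 = causal_idx
    else:
        c2 = None

    def one_trait(nn, tt, cidx, beta):
        G = panel.sample_genotypes(nn, rng)
        liab = rng.normal(scale=trait_sd, size=nn)
        if cidx is not None and beta != 0:
            liab = liab + G[:, cidx] * beta
        if tt == "case-control":
            thr = np.quantile(liab, 1 - prevalence)
            y = liab > thr
        else:
            y = liab
        return G, y

    G1, y1 = one_trait(n1, trait_types[0], c1, beta1)
    G2, y2 = one_trait(n2, trait_types[1], c2, beta2)
    t1 = _sumstats_from_panel(panel, G1, y1, study_ids[0], trait_types[0], n1)
    t2 = _sumstats_from_panel(panel, G2, y2, study_ids[1], trait_types[1], n2)
    truth = SyntheticTruth(
        hypothesis={region_id: scenario},
        causal_gwas={region_id: _vstr(panel.variants[c1]) if c1 is not None else None},
        causal_eqtl={region_id: _vstr(panel.variants[c2]) if c2 is not None else None},
        trait_sd=trait_sd,
        causal_maf={
            region_id: float(min(panel.freqs[causal_idx], 1 - panel.freqs[causal_idx]))
        },
    )
    return t1, t2, truth


# ---------------------------------------------------------------------------
# multi-study panel generation


@dataclass
class PanelConfig:
    """Desk-scale emulation of a multi-GWAS x multi-eQTL-study panel.

    Defaults reflect the structure of large published panels (several
    independent GWAS peaks per trait, eQTL studies spanning cell types,
    granularities, compositions and stimulation states) at sizes a laptop
    can simulate.  ``celltype_multipliers`` scale each cell type's
    colocalisation probability relative to ``base_coloc_prob``.
    """

    n_traits: int = 1
    peaks_per_trait: int = 4
    studies: list[StudyMeta] = field(default_factory=list)
    genes_per_region: int = 3
    base_coloc_prob: float = 0.3
    celltype_multipliers: dict = field(default_factory=dict)
    indep_eqtl_prob: float = 0.5
    coregulated_pair_rate: float = 0.3
    coreg_coloc_boost: float = 0.9
    coreg_loading: float = float(np.sqrt(0.6))
    enhancer_link_prob_sig: float = 0.4
    enhancer_link_prob_nonsig: float = 0.03
    crossmap_rate: float = 0.1
    n_variants: int = 60
    n_haplotypes: int = 400
    region_span: int = 600_000
    region_spacing: int = 3_000_000
    n_gwas: int = 4000
    gwas_beta: float = 0.35
    eqtl_beta: float = 0.6
    expression_samples: int = 200
    decay: float = 0.98
    maf_bounds: tuple[float, float] = (0.05, 0.5)

    @staticmethod
    def minimal() -> "PanelConfig":
        return PanelConfig(
            n_traits=1,
            peaks_per_trait=2,
            genes_per_region=2,
            studies=[
                StudyMeta("studyA", "CD4 T", "sorted", "controls", "resting", n=600),
                StudyMeta("studyB", "B", "single-cell", "patients_and_controls", "resting", n=400),
            ],
        )

    def validate(self) -> None:
        if not self.studies:
            raise ValueError("config needs at least one eQTL study")
        if self.coregulated_pair_rate > 0 and self.genes_per_region < 2:
            raise ValueError("coregulated pairs need >= 2 genes per region")


def _default_studies() -> list[StudyMeta]:
    # cell types recur across granularities/compositions so that design
    # covariates are identifiable alongside cell-type indicators
    return [
        StudyMeta("wb_bulk", "whole blood", "bulk", "controls", "resting", n=2000),
        StudyMeta("cd4_sorted", "CD4 T", "sorted", "controls", "resting", n=600),
        StudyMeta("cd4_sc", "CD4 T", "single-cell", "controls", "resting", n=400),
        StudyMeta("cd8_sorted", "CD8 T", "sorted", "controls", "resting", n=600),
        StudyMeta("b_sc", "B", "single-cell", "controls", "resting", n=400),
        StudyMeta("b_sorted", "B", "sorted", "patients_and_controls", "resting", n=500),
        StudyMeta("mono_pat", "Monocyte", "sorted", "patients_and_controls", "resting", n=500),
        StudyMeta("nk_stim", "NK", "sorted", "controls", "stimulated", n=400),
        StudyMeta("nk_sorted", "NK", "sorted", "controls", "resting", n=450),
    ]


@dataclass
class SyntheticBundle:
    """All module inputs for one simulated panel, plus the truth."""

    gwas: dict  # gwas_id -> SumStatsTable
    eqtl_panel: dict  # study_id -> {gene_id -> SumStatsTable}
    study_meta: dict  # study_id -> StudyMeta
    gene_annotation: dict  # gene_id -> (chrom, tss, strand)
    gene_biotype: dict
    leads: list  # (trait_id, VariantKey, p)
    expression: dict  # cell_type -> DataFrame (gene x sample)
    enhancer_links: list
    crossmap: list
    panels: dict  # region_id -> LDPanel
    region_of_gene: dict
    truth: SyntheticTruth
    config: PanelConfig

    def write(self, outdir) -> None:
        """Write the bundle as plain-text files round-tripping the readers."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = {
            "chrom": "CHR", "pos": "POS", "ref": "REF", "alt": "ALT",
            "beta": "BETA", "se": "SE", "pvalue": "P", "maf": "MAF", "n": "N",
        }
        for gid, t in self.gwas.items():
            t.data.rename(columns=header).to_csv(out / f"gwas_{gid}.tsv", sep="\t", index=False)
        for sid, genes in self.eqtl_panel.items():
            d = out / "eqtl" / sid
            d.mkdir(parents=True, exist_ok=True)
            for gene, t in genes.items():
                t.data.rename(columns=header).to_csv(d / f"{gene}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"trait": tr, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "p": p}
                for tr, v, p in self.leads
            ]
        ).to_csv(out / "leads.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": g,
                    "chrom": c,
                    "tss": t,
                    "strand": s,
                    "biotype": self.gene_biotype.get(g, "protein_coding"),
                }
                for g, (c, t, s) in self.gene_annotation.items()
            ]
        ).to_csv(out / "genes.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(s) for s in self.study_meta.values()]).to_csv(
            out / "study_meta.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"chrom": l.chrom, "start": l.start, "end": l.end, "gene_id": l.gene_id,
                 "score": l.score, "cell_type": l.cell_type}
                for l in self.enhancer_links
            ]
        ).to_csv(out / "enhancer_links.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_a": e.gene_a, "gene_b": e.gene_b, "count": e.count} for e in self.crossmap]
        ).to_csv(out / "crossmap.tsv", sep="\t", index=False)
        for ct, mat in self.expression.items():
            mat.to_csv(out / f"expression_{ct.replace(' ', '_')}.tsv", sep="\t")
        truth = asdict(self.truth)
        truth["test_hypothesis"] = {"|".join(k): v for k, v in self.truth.test_hypothesis.items()}
        truth["causal_eqtl"] = {
            ("|".join(k) if isinstance(k, tuple) else k): v for k, v in self.truth.causal_eqtl.items()
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def simulate_study_panel(config: PanelConfig | None = None, seed=0) -> SyntheticBundle:
    """Generate the full multi-study input bundle with known truth."""
    cfg = config or PanelConfig(studies=_default_studies())
    if not cfg.studies:
        cfg.studies = _default_studies()
    cfg.validate()
    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    streams = root.spawn(cfg.n_traits * cfg.peaks_per_trait + 3)
    rng_global = np.random.default_rng(streams[-1])

    truth = SyntheticTruth(
        enrichment_multipliers=dict(cfg.celltype_multipliers),
        link_probs=(cfg.enhancer_link_prob_sig, cfg.enhancer_link_prob_nonsig),
        study_n={s.study_id: s.n for s in cfg.studies},
    )
    gwas_tables: dict[str, SumStatsTable] = {}
    eqtl_panel: dict[str, dict[str, SumStatsTable]] = {s.study_id: {} for s in cfg.studies}
    annotation: dict[str, tuple] = {}
    biotype: dict[str, str] = {}
    leads = []
    panels: dict[str, LDPanel] = {}
    region_of_gene: dict[str, str] = {}
    coloc_truth: dict[tuple, set] = {}  # (region, cell_type) -> colocalising genes
    region_genes: dict[str, list[str]] = {}

    k = 0
    for ti in range(cfg.n_traits):
        trait = f"gwas{ti}"
        gwas_frames = []
        for pi in range(cfg.peaks_per_trait):
            rng = np.random.default_rng(streams[k])
            k += 1
            region_id = f"{trait}_r{pi}"
            start = 1_000_000 + (ti * cfg.peaks_per_trait + pi) * cfg.region_spacing
            panel = simulate_ld_panel(
                cfg.n_variants, cfg.n_haplotypes, cfg.decay, cfg.region_span,
                rng, chrom="1", start=start, maf_bounds=cfg.maf_bounds,
            )
            panels[region_id] = panel
            m = len(panel.variants)
            mid = np.arange(m // 4, 3 * m // 4)
            causal = int(mid[np.argmax(panel.freqs[mid] * (1 - panel.freqs[mid]))])
            truth.causal_gwas[region_id] = _vstr(panel.variants[causal])
            truth.causal_maf[region_id] = float(
                min(panel.freqs[causal], 1 - panel.freqs[causal])
            )
            truth.hypothesis[region_id] = "H4"
            G = panel.sample_genotypes(cfg.n_gwas, rng)
            y = G[:, causal] * cfg.gwas_beta + rng.standard_normal(cfg.n_gwas)
            gtab = _sumstats_from_panel(panel, G, y, trait, "quantitative", cfg.n_gwas)
            gwas_frames.append(gtab.data)
            lead_p = float(gtab.data["pvalue"].iloc[int(np.argmin(gtab.data["pvalue"]))])
            leads.append((trait, panel.variants[int(np.argmin(gtab.data["pvalue"].values))], lead_p))

            # genes and their TSS layout around the region
            center = start + cfg.region_span // 2
            genes = []
            for gi in range(cfg.genes_per_region):
                gene = f"{region_id}_g{gi}"
                offset = int(rng.integers(-cfg.region_span // 2, cfg.region_span // 2))
                annotation[gene] = ("1", center + offset, "+" if gi % 2 == 0 else "-")
                biotype[gene] = "protein_coding" if rng.random() > 0.15 else "ncRNA"
                genes.append(gene)
                region_of_gene[gene] = region_id
            region_genes[region_id] = genes

            coreg: list[tuple[str, str]] = []
            for gi in range(0, cfg.genes_per_region - 1, 2):
                if rng.random() < cfg.coregulated_pair_rate:
                    coreg.append((genes[gi], genes[gi + 1]))
            truth.coregulated_pairs.extend(coreg)
            partner = {a: b for a, b in coreg} | {b: a for a, b in coreg}

            for s in cfg.studies:
                mult = cfg.celltype_multipliers.get(s.cell_type, 1.0)
                prob = min(1.0, cfg.base_coloc_prob * mult)
                coloc_genes: set[str] = set()
                for gene in genes:
                    if gene in coloc_genes:
                        continue
                    if rng.random() < prob:
                        coloc_genes.add(gene)
                        if gene in partner and rng.random() < cfg.coreg_coloc_boost:
                            coloc_genes.add(partner[gene])
                key = (region_id, s.cell_type)
                coloc_truth.setdefault(key, set()).update(coloc_genes)
                for gene in genes:
                    tkey = (trait, s.study_id, gene)
                    if gene in coloc_genes:
                        c2, hyp = causal, "H4"
                    elif rng.random() < cfg.indep_eqtl_prob:
                        c2, hyp = _pick_low_ld_partner(panel, causal, rng), "H3"
                    else:
                        c2, hyp = None, "H1"
                    truth.test_hypothesis[tkey] = hyp
                    truth.causal_eqtl[tkey] = _vstr(panel.variants[c2]) if c2 is not None else None
                    Ge = panel.sample_genotypes(s.n, rng)
                    ye = rng.standard_normal(s.n)
                    if c2 is not None:
                        ye = ye + Ge[:, c2] * cfg.eqtl_beta
                    eqtl_panel[s.study_id][gene] = _sumstats_from_panel(
                        panel, Ge, ye, s.study_id, "quantitative", s.n
                    )
        gwas_tables[trait] = SumStatsTable(
            trait, "quantitative", pd.concat(gwas_frames, ignore_index=True)
        )

    # expression matrices per cell type, co-regulated pairs share a latent factor
    expression: dict[str, pd.DataFrame] = {}
    coreg_partner = {a: b for a, b in truth.coregulated_pairs}
    coreg_partner.update({b: a for a, b in truth.coregulated_pairs})
    all_genes = sorted(annotation)
    for ct in sorted({s.cell_type for s in cfg.studies}):
        rng = rng_global
        ns = cfg.expression_samples
        z = pd.DataFrame(
            rng.standard_normal((len(all_genes), ns)), index=all_genes
        )
        lam = cfg.coreg_loading
        for a, b in truth.coregulated_pairs:
            f = rng.standard_normal(ns)
            for g in (a, b):
                z.loc[g] = lam * f + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal(ns)
        mu = rng.normal(2.0, 0.5, size=len(all_genes))
        expression[ct] = np.exp(z.add(mu, axis=0))
        expression[ct].columns = [f"s{i}" for i in range(ns)]

    # enhancer links anchored on each region's GWAS causal variant
    links: list[EnhancerLink] = []
    rng = rng_global
    cell_types = sorted({s.cell_type for s in cfg.studies})
    for region_id, panel in panels.items():
        cvar = [v for v in panel.variants if _vstr(v) == truth.causal_gwas[region_id]][0]
        e_start, e_end = cvar.pos - 1000, cvar.pos + 1000  # 0-based half-open
        # the enhancer element always has at least one active target beyond
        # the tested genes, so peaks are not selected on their genes' links
        links.append(
            EnhancerLink(cell_types[0], "1", e_start, e_end, f"{region_id}_distal", 0.9)
        )
        for gene in region_genes[region_id]:
            for ct in cell_types:
                sig = gene in coloc_truth.get((region_id, ct), set())
                p_link = cfg.enhancer_link_prob_sig if sig else cfg.enhancer_link_prob_nonsig
                if rng.random() < p_link:
                    links.append(
                        EnhancerLink(ct, "1", e_start, e_end, gene, float(rng.uniform(0.2, 1.0)))
                    )
                elif rng.random() < 0.1:  # inactive background link below threshold
                    links.append(
                        EnhancerLink(ct, "1", e_start, e_end, gene, float(rng.uniform(0.0, 0.15)))
                    )

    # cross-mappability contamination between same-region gene pairs
    crossmap: list[CrossmapEntry] = []
    for region_id, genes in region_genes.items():
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < cfg.crossmap_rate:
                    crossmap.append(
                        CrossmapEntry(genes[i], genes[j], float(1 + rng.poisson(5)))
                    )

    meta = {s.study_id: s for s in cfg.studies}
    return SyntheticBundle(
        gwas=gwas_tables,
        eqtl_panel=eqtl_panel,
        study_meta=meta,
        gene_annotation=annotation,
        gene_biotype=biotype,
        leads=leads,
        expression=expression,
        enhancer_links=links,
        crossmap=crossmap,
        panels=panels,
        region_of_gene=region_of_gene,
        truth=truth,
        config=cfg,
    )


def simulate_test_flags(
    n_peaks: int,
    studies: Sequence[StudyMeta],
    genes_per_peak: int = 3,
    base_rate: float = 0.2,
    or_by_celltype: Mapping[str, float] | None = None,
    or_single_cell: float = 1.0,
    or_patients: float = 1.0,
    or_stimulated: float = 1.0,
    maf_log_or: float = 0.0,
    concentrated: bool = False,
    alpha: float = 0.9,
    seed=0,
) -> pd.DataFrame:
    """Test-level peak-gene matrix drawn from a logistic truth model.

    Each row is one (peak, gene, study) colocalisation test; the
    significance flag is Bernoulli with logit = logit(base_rate)
    + log OR terms for the study's cell type, design covariates and the
    peak lead MAF.  ``concentrated`` restricts colocalisation to one
    designated gene per peak (co-regulation-free truth for the
    randomisation-null analyses).  PP(H4) values are drawn consistently
    with the flag at threshold ``alpha``.
    """
    rng = _rng(seed)
    ors = dict(or_by_celltype or {})
    rows = []
    base_logit = np.log(base_rate / (1 - base_rate))
    for pi in range(n_peaks):
        pid = f"peak{pi:04d}"
        maf = float(rng.uniform(0.05, 0.5))
        target_gene = int(rng.integers(genes_per_peak))
        for s in studies:
            for gi in range(genes_per_peak):
                logit = base_logit + np.log(ors.get(s.cell_type, 1.0))
                if s.granularity == "single-cell":
                    logit += np.log(or_single_cell)
                if s.composition == "patients_and_controls":
                    logit += np.log(or_patients)
                if s.stimulation == "stimulated":
                    logit += np.log(or_stimulated)
                logit += maf_log_or * maf
                p = 1 / (1 + np.exp(-logit))
                sig = rng.random() < p
                if concentrated and gi != target_gene:
                    sig = False
                pp = rng.uniform(alpha, 1.0) if sig else rng.uniform(0.0, alpha)
                rows.append(
                    {
                        "peak_id": pid,
                        "gene_id": f"{pid}_g{gi}",
                        "study_id": s.study_id,
                        "cell_type": s.cell_type,
                        "pp_h4": pp,
                        "significant": sig,
                        "maf": maf,
                    }
                )
    return pd.DataFrame(rows)


def truth_report(
    truth: SyntheticTruth,
    results: Sequence,
    maf_bins: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> dict:
    """Empirical FDR and power of the H4 calls against the generative truth.

    Results are annotated ColocResult objects whose (gwas_id, study_id,
    gene_id) keys appear in ``truth.test_hypothesis`` (panel truth) or whose
    region ids appear in ``truth.hypothesis`` (region-pair truth).  Power is
    stratified by causal-variant MAF bin and by eQTL sample size.
    """
    calls, labels, mafs, n2s = [], [], [], []
    for r in results:
        key = (r.gwas_id, r.study_id, r.gene_id)
        if key in truth.test_hypothesis:
            hyp = truth.test_hypothesis[key]
            region = key[2].rsplit("_g", 1)[0]
        elif r.gene_id in truth.hypothesis:
            hyp, region = truth.hypothesis[r.gene_id], r.gene_id
        else:
            continue
        calls.append(bool(r.significant))
        labels.append(hyp)
        mafs.append(truth.causal_maf.get(region, np.nan))
        n2s.append(truth.study_n.get(r.study_id, np.nan))
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    mafs = np.asarray(mafs, dtype=float)
    n2s = np.asarray(n2s, dtype=float)

    n_called = int(calls.sum())
    fdr = float(np.mean(labels[calls] != "H4")) if n_called else None
    is_h4 = labels == "H4"
    power = float(calls[is_h4].mean()) if is_h4.any() else None

    power_by_maf = {}
    for lo, hi in zip(maf_bins[:-1], maf_bins[1:]):
        sel = is_h4 & (mafs >= lo) & (mafs < hi)
        if sel.any():
            power_by_maf[f"[{lo},{hi})"] = float(calls[sel].mean())
    power_by_n2 = {}
    for n2 in sorted(set(n2s[np.isfinite(n2s)])):
        sel = is_h4 & (n2s == n2)
        if sel.any():
            power_by_n2[int(n2)] = float(calls[sel].mean())
    return {
        "n_tests": int(calls.size),
        "n_called": n_called,
        "empirical_fdr": fdr,
        "power": power,
        "power_by_maf": power_by_maf,
        "power_by_n2": power_by_n2,
    }
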