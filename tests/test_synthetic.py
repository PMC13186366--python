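import numpy as np
import pandas as pd
import pytest

from colocgap.coloc import (
    call_significant,
    coloc_abf,
    fdr_threshold,
    run_region_tests,
)
from colocgap.finemap import wakefield_log_abf
from colocgap.sumstats import read_sumstats, select_egenes
from colocgap.synthetic import (
    PanelConfig,
    simulate_ld_panel,
    simulate_region_pair,
    simulate_study_panel,
    simulate_test_flags,
    truth_report,
)


def pp_for_pair(gwas, eqtl, prior_sd=0.15):
    l1 = wakefield_log_abf(gwas.data["beta"], gwas.data["se"], prior_sd)
    l2 = wakefield_log_abf(eqtl.data["beta"], eqtl.data["se"], prior_sd)
    return coloc_abf(l1, l2)


class TestLdPanel:
    def test_zero_decay_gives_independent_variants(self):
        panel = simulate_ld_panel(10, 10_000, 0.0, 100_000, seed=1)
        r2s = [panel.r2(j, j + 1) for j in range(9)]
        assert max(r2s) < 0.02

    def test_positive_decay_gives_ld(self):
        panel = simulate_ld_panel(10, 4000, 0.99, 20_000, seed=2)
        assert np.nanmean([panel.r2(j, j + 1) for j in range(9)]) > 0.3

    def test_seed_determinism(self):
        a = simulate_ld_panel(15, 100, 0.9, 50_000, seed=3)
        b = simulate_ld_panel(15, 100, 0.9, 50_000, seed=3)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.variants == b.variants

    def test_maf_bounds_respected(self):
        panel = simulate_ld_panel(50, 2000, 0.5, 100_000, seed=4, maf_bounds=(0.01, 0.5))
        maf = np.minimum(panel.freqs, 1 - panel.freqs)
        assert maf.min() > 0.0 and maf.max() <= 0.55  # sampling noise on targets

    def test_invalid_decay(self):
        with pytest.raises(ValueError):
            simulate_ld_panel(5, 100, 1.0, 1000, seed=0)


class TestRegionPair:
    def test_h0_pvalues_uniform(self):
        panel = simulate_ld_panel(1000, 400, 0.0, 4_000_000, seed=5)
        gwas, _, _ = simulate_region_pair(panel, "H0", 800, 100, 0.0, 0.0, seed=6)
        frac = float((gwas.data["pvalue"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.025)

    def test_h4_colocalises_downstream(self):
        panel = simulate_ld_panel(40, 400, 0.97, 200_000, seed=7)
        gwas, eqtl, truth = simulate_region_pair(
            panel, "H4", 10_000, 10_000, 0.35, 0.35, seed=8
        )
        pp = pp_for_pair(gwas, eqtl)
        assert pp[4] > 0.9
        region = next(iter(truth.hypothesis))
        assert truth.causal_gwas[region] == truth.causal_eqtl[region]

    def test_h3_separated_causals_favour_h3(self):
        panel = simulate_ld_panel(40, 400, 0.9, 400_000, seed=9)
        gwas, eqtl, truth = simulate_region_pair(
            panel, "H3", 10_000, 10_000, 0.35, 0.35, seed=10, h3_max_r2=0.05
        )
        pp = pp_for_pair(gwas, eqtl)
        assert pp[3] > pp[4]
        region = next(iter(truth.hypothesis))
        assert truth.causal_gwas[region] != truth.causal_eqtl[region]

    def test_case_control_trait(self):
        panel = simulate_ld_panel(30, 400, 0.95, 100_000, seed=11)
        gwas, _, _ = simulate_region_pair(
            panel, "H1", 8000, 100, 0.5, 0.0, trait_types=("case-control", "quantitative"),
            seed=12,
        )
        assert gwas.trait_type == "case-control"
        assert float(gwas.data["pvalue"].min()) < 5e-8

    def test_unknown_scenario(self):
        panel = simulate_ld_panel(5, 100, 0.0, 1000, seed=0)
        with pytest.raises(ValueError):
            simulate_region_pair(panel, "H5", 10, 10, 0, 0)


class TestStudyPanel:
    def test_minimal_config_round_trips(self, tmp_path):
        bundle = simulate_study_panel(PanelConfig.minimal(), seed=13)
        bundle.write(tmp_path)
        # every written summary-statistics file re-parses without drops
        for f in sorted(tmp_path.glob("gwas_*.tsv")):
            t = read_sumstats(f)
            assert t.validation_report["n_dropped"] == 0
        eqtl_files = sorted((tmp_path / "eqtl").rglob("*.tsv"))
        assert eqtl_files
        for f in eqtl_files:
            assert read_sumstats(f).validation_report["n_dropped"] == 0
        for name in ("leads.tsv", "genes.tsv", "study_meta.tsv",
                     "enhancer_links.tsv", "crossmap.tsv", "truth.json"):
            assert (tmp_path / name).exists()

    def test_truth_conservation(self):
        cfg = PanelConfig.minimal()
        bundle = simulate_study_panel(cfg, seed=14)
        n_regions = cfg.n_traits * cfg.peaks_per_trait
        assert len(bundle.truth.hypothesis) == n_regions
        assert len(bundle.panels) == n_regions
        n_tests = n_regions * len(cfg.studies) * cfg.genes_per_region
        assert len(bundle.truth.test_hypothesis) == n_tests

    def test_seed_determinism(self):
        a = simulate_study_panel(PanelConfig.minimal(), seed=15)
        b = simulate_study_panel(PanelConfig.minimal(), seed=15)
        pd.testing.assert_frame_equal(
            a.gwas["gwas0"].data, b.gwas["gwas0"].data
        )
        assert a.truth.test_hypothesis == b.truth.test_hypothesis

    def test_inconsistent_config_errors(self):
        cfg = PanelConfig.minimal()
        cfg.genes_per_region = 1
        cfg.coregulated_pair_rate = 0.5
        with pytest.raises(ValueError):
            simulate_study_panel(cfg, seed=0)


class TestPowerMonotonicity:
    def test_mean_pph4_nondecreasing_in_eqtl_sample_size(self):
        rng = np.random.default_rng(30)
        means = []
        for n2 in (200, 600, 2000):
            pps = []
            for _ in range(40):
                panel = simulate_ld_panel(30, 300, 0.97, 150_000, rng)
                g, e, _ = simulate_region_pair(
                    panel, "H4", 5000, n2, 0.25, 0.25, seed=rng
                )
                pps.append(pp_for_pair(g, e)[4])
            means.append(float(np.mean(pps)))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
        assert means[2] > means[0]


class TestTestFlags:
    def test_enrichment_shifts_rate(self):
        from colocgap.sumstats import StudyMeta

        studies = [
            StudyMeta("a", "B", "sorted", "controls", "resting", n=100),
            StudyMeta("b", "NK", "sorted", "controls", "resting", n=100),
        ]
        m = simulate_test_flags(
            800, studies, base_rate=0.2, or_by_celltype={"B": 3.0}, seed=16
        )
        rate_b = m[m["cell_type"] == "B"]["significant"].mean()
        rate_nk = m[m["cell_type"] == "NK"]["significant"].mean()
        assert rate_b > rate_nk

    def test_pp_consistent_with_flag(self):
        from colocgap.sumstats import StudyMeta

        studies = [StudyMeta("a", "B", "sorted", "controls", "resting", n=100)]
        m = simulate_test_flags(50, studies, alpha=0.9, seed=17)
        assert (m[m["significant"]]["pp_h4"] > 0.9).all()
        assert (m[~m["significant"].astype(bool)]["pp_h4"] <= 0.9).all()


class TestTruthReport:
    def _run_panel(self, seed):
        bundle = simulate_study_panel(PanelConfig.minimal(), seed=seed)
        egenes = []
        for sid, tables in bundle.eqtl_panel.items():
            egenes.extend(
                select_egenes(tables, annotation=bundle.gene_annotation,
                              biotypes=bundle.gene_biotype)
            )
        results = []
        for gid, gtab in bundle.gwas.items():
            res, _ = run_region_tests(gtab, bundle.eqtl_panel, egenes)
            results.extend(res)
        return bundle, results

    def test_report_fields_and_ranges(self):
        bundle, results = self._run_panel(18)
        calib = fdr_threshold([r.pp_h4 for r in results])
        call_significant(results, calib)
        rep = truth_report(bundle.truth, results)
        assert rep["n_tests"] == len(results)
        if rep["empirical_fdr"] is not None:
            assert 0 <= rep["empirical_fdr"] <= 1
        assert rep["power"] is None or 0 <= rep["power"] <= 1
        for v in rep["power_by_n2"].values():
            assert 0 <= v <= 1

    def test_zero_calls_reports_absent_fdr(self):
        bundle, results = self._run_panel(19)
        call_significant(results, 1.0)  # nothing exceeds 1.0 strictly
        rep = truth_report(bundle.truth, results)
        assert rep["n_called"] == 0
        assert rep["empirical_fdr"] is None

    def test_perfect_caller(self):
        bundle, results = self._run_panel(20)
        for r in results:
            key = (r.gwas_id, r.study_id, r.gene_id)
            r.significant = bundle.truth.test_hypothesis[key] == "H4"
        rep = truth_report(bundle.truth, results)
        assert rep["empirical_fdr"] == 0.0
        assert rep["power"] == 1.0
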