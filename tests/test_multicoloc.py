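import numpy as np
import pandas as pd
import pytest

from colocgap.multicoloc import (
    CrossmapEntry,
    EnhancerLink,
    build_control_pairs,
    coregulation_contrasts,
    crossmap_filter,
    enhancer_link_rates,
    genes_per_peak,
    lead_snp_r2,
    randomisation_null,
    same_celltype_pair_enrichment,
    threshold_sensitivity,
)
from colocgap.sumstats import StudyMeta
from colocgap.synthetic import simulate_ld_panel, simulate_test_flags


def matrix_from_counts(counts):
    """Peaks with the given numbers of distinct significant genes (plus one
    non-significant test each)."""
    rows = []
    for i, c in enumerate(counts):
        pid = f"pk{i}"
        for g in range(max(c, 1)):
            rows.append(
                {
                    "peak_id": pid,
                    "gene_id": f"{pid}_g{g}",
                    "study_id": "s1",
                    "cell_type": "B",
                    "pp_h4": 0.95 if g < c else 0.1,
                    "significant": g < c,
                }
            )
    return pd.DataFrame(rows)


class TestGenesPerPeak:
    def test_all_single_gene(self):
        counts, hist, frac = genes_per_peak(matrix_from_counts([1, 1, 1]))
        assert frac == 0.0

    def test_worked_fraction(self):
        _, _, frac = genes_per_peak(matrix_from_counts([1, 1, 2, 3, 0]))
        assert frac == pytest.approx(0.5)

    def test_distinct_genes_not_tests(self):
        m = matrix_from_counts([2])
        dup = m[m["significant"]].copy()
        dup["study_id"] = "s2"
        m2 = pd.concat([m, dup], ignore_index=True)
        assert genes_per_peak(m)[2] == genes_per_peak(m2)[2]


class TestRandomisationNull:
    def test_single_test_per_peak_identical_curves(self):
        m = matrix_from_counts([1, 1, 1, 0, 0])
        m = m.groupby("peak_id", as_index=False).first()
        m["study_id"] = "s1"
        other = m.copy()
        other["study_id"] = "s2"
        other["significant"] = False
        other["pp_h4"] = 0.1
        other["gene_id"] = m["gene_id"]  # same gene tested by both studies
        mm = pd.concat([m, other], ignore_index=True)
        # permuting pp within a peak across studies of the SAME gene cannot
        # change the distinct-gene count at the end of the curve
        out = randomisation_null(mm, alpha=0.9, study_order_iters=10, seed=0)
        np.testing.assert_allclose(out["observed_final"], out["permuted_final"])

    def test_concentrated_truth_observed_below_permuted(self):
        studies = [
            StudyMeta(f"s{i}", "B", "sorted", "controls", "resting", n=500)
            for i in range(10)
        ]
        m = simulate_test_flags(
            60, studies, genes_per_peak=4, base_rate=0.4, concentrated=True, seed=9
        )
        out = randomisation_null(m, alpha=0.9, study_order_iters=50, seed=10)
        assert out["permuted_final_median"] > out["observed_final_median"]
        frac = np.mean(out["permuted_final"] > out["observed_final"])
        assert frac >= 0.95

    def test_deterministic_under_seed(self):
        m = matrix_from_counts([2, 1, 3])
        m2 = m.copy()
        m2["study_id"] = "s2"
        mm = pd.concat([m, m2], ignore_index=True)
        a = randomisation_null(mm, alpha=0.5, study_order_iters=5, seed=42)
        b = randomisation_null(mm, alpha=0.5, study_order_iters=5, seed=42)
        np.testing.assert_array_equal(a["observed_curves"], b["observed_curves"])
        np.testing.assert_array_equal(a["permuted_curves"], b["permuted_curves"])

    def test_permutation_preserves_pp_multiset(self):
        # the permuted analysis must leave each peak's PP(H4) multiset intact:
        # at alpha below every value, curves coincide
        m = matrix_from_counts([3, 2])
        m2 = m.copy()
        m2["study_id"] = "s2"
        mm = pd.concat([m, m2], ignore_index=True)
        out = randomisation_null(mm, alpha=0.0, study_order_iters=5, seed=1)
        np.testing.assert_allclose(out["observed_curves"], out["permuted_curves"])


class TestThresholdSensitivity:
    def test_extremes(self):
        m = matrix_from_counts([2, 1])
        t = threshold_sensitivity(m, [0.0, 1.0])
        assert t["peaks_ge1"].iloc[0] == 2  # every pp_h4 > 0
        assert (t[t["alpha"] == 1.0][["peaks_ge1", "peaks_ge2", "peaks_ge3"]] == 0).all().all()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        m = matrix_from_counts([3, 2, 2, 1, 1, 0])
        m["pp_h4"] = rng.uniform(0, 1, len(m))
        t = threshold_sensitivity(m, np.linspace(0, 1, 21))
        for col in ("peaks_ge1", "peaks_ge2", "peaks_ge3"):
            assert (np.diff(t[col]) <= 0).all()


class TestCrossmapFilter:
    def test_no_entries_identity(self):
        m = matrix_from_counts([2, 1])
        out, report = crossmap_filter(m, [])
        pd.testing.assert_frame_equal(out, m)
        assert report.empty

    def test_lower_pp_gene_excluded(self):
        m = pd.DataFrame(
            {
                "peak_id": ["p", "p"],
                "gene_id": ["A", "B"],
                "study_id": ["s", "s"],
                "cell_type": ["B", "B"],
                "pp_h4": [0.99, 0.90],
                "significant": [True, True],
            }
        )
        out, report = crossmap_filter(m, [CrossmapEntry("A", "B", 3)])
        assert report["gene_id"].tolist() == ["B"]
        assert out["gene_id"].tolist() == ["A"]

    def test_chain_excludes_middle_only(self):
        m = pd.DataFrame(
            {
                "peak_id": ["p"] * 3,
                "gene_id": ["A", "B", "C"],
                "study_id": ["s"] * 3,
                "cell_type": ["B"] * 3,
                "pp_h4": [0.99, 0.90, 0.95],
                "significant": [True] * 3,
            }
        )
        out, report = crossmap_filter(
            m, [CrossmapEntry("A", "B", 2), CrossmapEntry("B", "C", 1)]
        )
        assert report["gene_id"].tolist() == ["B"]
        assert sorted(out["gene_id"]) == ["A", "C"]

    def test_single_significant_gene_untouched(self):
        m = matrix_from_counts([1])
        out, _ = crossmap_filter(m, [CrossmapEntry("pk0_g0", "pk0_g1", 5)])
        pd.testing.assert_frame_equal(out, m)


class TestBuildControlPairs:
    def _m(self, sig_genes, nonsig_genes, ct="B"):
        rows = []
        for g in sig_genes:
            rows.append(
                {"peak_id": "p", "gene_id": g, "study_id": "s", "cell_type": ct,
                 "pp_h4": 0.95, "significant": True}
            )
        for g in nonsig_genes:
            rows.append(
                {"peak_id": "p", "gene_id": g, "study_id": "s", "cell_type": ct,
                 "pp_h4": 0.2, "significant": False}
            )
        return pd.DataFrame(rows)

    def test_no_control_available_drops_pair(self):
        pairs, dropped = build_control_pairs(self._m(["A", "B"], []))
        assert pairs.empty
        assert dropped["reason"].tolist() == ["no eligible control"]

    def test_control_pair_traces_rule(self):
        pairs, _ = build_control_pairs(self._m(["A", "B"], ["C"]), seed=0)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["control_gene_b"] == "C"
        assert row["control_gene_a"] in {"A", "B"}

    def test_controls_used_once_and_counts_equal(self):
        pairs, dropped = build_control_pairs(self._m(["A", "B", "C"], ["X", "Y"]), seed=1)
        # 3 case pairs but only 2 eligible controls: one pair dropped
        assert len(pairs) == 2 and len(dropped) == 1
        assert pairs["control_gene_b"].is_unique

    def test_seed_determinism(self):
        m = self._m(["A", "B", "C"], ["X", "Y", "Z"])
        pd.testing.assert_frame_equal(
            build_control_pairs(m, seed=7)[0], build_control_pairs(m, seed=7)[0]
        )


class TestCoregulationContrasts:
    @staticmethod
    def _pairs_and_expression(loading, n_pairs=30, n_samples=150, seed=0):
        rng = np.random.default_rng(seed)
        rows, genes = [], {}
        for i in range(n_pairs):
            rows.append(
                {
                    "peak_id": f"p{i}",
                    "case_gene_a": f"ca{i}", "case_gene_b": f"cb{i}",
                    "case_cell_type_a": "B", "case_cell_type_b": "B",
                    "control_gene_a": f"ca{i}", "control_gene_b": f"x{i}",
                    "control_cell_type": "B",
                }
            )
        all_genes = [g for i in range(n_pairs) for g in (f"ca{i}", f"cb{i}", f"x{i}")]
        z = {g: rng.standard_normal(n_samples) for g in all_genes}
        for i in range(n_pairs):
            f = rng.standard_normal(n_samples)
            for g in (f"ca{i}", f"cb{i}"):
                z[g] = loading * f + np.sqrt(1 - loading**2) * rng.standard_normal(n_samples)
        expr = pd.DataFrame({g: np.exp(2 + v) for g, v in z.items()}).T
        tss = {g: ("1", 1000 * j) for j, g in enumerate(all_genes)}
        return pd.DataFrame(rows), {"B": expr}, tss

    def test_coregulated_cases_show_higher_r2(self):
        pairs, expr, tss = self._pairs_and_expression(np.sqrt(0.6), seed=3)
        out = coregulation_contrasts(pairs, expr, tss)
        assert out["delta_r2"] > 0
        assert out["p_r2"] < 0.05

    def test_identical_vectors_r2_one(self):
        pairs, expr, tss = self._pairs_and_expression(0.3, n_pairs=2, seed=4)
        expr["B"].loc["cb0"] = expr["B"].loc["ca0"]
        out = coregulation_contrasts(pairs, expr, tss)
        case0 = out["table"][(out["table"]["peak_id"] == "p0") & (out["table"]["case"] == 1)]
        assert case0["r2"].iloc[0] == pytest.approx(1.0)

    def test_constant_expression_pair_dropped(self):
        pairs, expr, tss = self._pairs_and_expression(0.3, n_pairs=3, seed=5)
        expr["B"].loc["ca0"] = 1.0
        out = coregulation_contrasts(pairs, expr, tss)
        assert out["n_dropped"] == 2  # ca0 appears in the case and control pair


class TestSameCelltypePairEnrichment:
    @staticmethod
    def _celltype_coupled_matrix(n_peaks, rate_hi=0.55, rate_lo=0.15, seed=11):
        # significance rate shared within each (peak, cell type): same-cell-type
        # pairs co-colocalise more often than cross-cell-type pairs
        rng = np.random.default_rng(seed)
        studies = {"s1": "B", "s2": "B", "s3": "CD4 T", "s4": "CD4 T"}
        rows = []
        for i in range(n_peaks):
            pid = f"pk{i}"
            rate = {
                ct: rate_hi if rng.random() < 0.4 else rate_lo
                for ct in {"B", "CD4 T"}
            }
            for sid, ct in studies.items():
                for g in range(2):
                    sig = rng.random() < rate[ct]
                    rows.append(
                        {"peak_id": pid, "gene_id": f"{pid}_g{g}", "study_id": sid,
                         "cell_type": ct, "pp_h4": 0.95 if sig else 0.2,
                         "significant": sig}
                    )
        return pd.DataFrame(rows)

    def test_same_celltype_effect_recovered(self):
        m = self._celltype_coupled_matrix(250)
        out = same_celltype_pair_enrichment(m)
        assert out["odds_ratio"] > 1.0
        assert out["p"] < 0.05

    def test_constant_indicator_warns(self):
        studies = [StudyMeta("s1", "B", "sorted", "controls", "resting", n=500)]
        m = simulate_test_flags(30, studies, genes_per_peak=2, base_rate=0.4, seed=13)
        with pytest.warns(UserWarning, match="same-cell-type"):
            out = same_celltype_pair_enrichment(m)
        assert np.isnan(out["odds_ratio"])

    def test_permuted_flags_near_null(self):
        studies = [
            StudyMeta("s1", "B", "sorted", "controls", "resting", n=500),
            StudyMeta("s2", "CD4 T", "sorted", "controls", "resting", n=500),
            StudyMeta("s3", "B", "sorted", "controls", "resting", n=500),
        ]
        m = simulate_test_flags(200, studies, genes_per_peak=2, base_rate=0.3, seed=14)
        rng = np.random.default_rng(15)
        m["significant"] = rng.permutation(m["significant"].values)
        out = same_celltype_pair_enrichment(m)
        assert abs(out["log_or"]) < 0.4


class TestLeadSnpR2:
    def test_self_pair_is_one(self, small_panel):
        assert lead_snp_r2(small_panel.haplotypes, [(3, 3)])[0] == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        panel = simulate_ld_panel(2, 40_000, 0.0, 10_000, seed=17)
        r2 = lead_snp_r2(panel.haplotypes, [(0, 1)])[0]
        assert r2 < 0.01

    def test_symmetry_and_monomorphic(self, small_panel):
        a = lead_snp_r2(small_panel.haplotypes, [(0, 5)])[0]
        b = lead_snp_r2(small_panel.haplotypes, [(5, 0)])[0]
        assert a == pytest.approx(b)
        H = small_panel.haplotypes.copy()
        H[:, 2] = 0
        assert lead_snp_r2(H, [(2, 3)])[0] is None


class TestEnhancerLinkRates:
    @staticmethod
    def _generate(p_sig=0.4, p_nonsig=0.03, n_peaks=150, seed=20):
        rng = np.random.default_rng(seed)
        rows, links, leads = [], [], {}
        for i in range(n_peaks):
            pid = f"pk{i}"
            lead_pos = 10_000 * (i + 1)
            leads[pid] = ("1", lead_pos)
            e_start, e_end = lead_pos - 100, lead_pos + 100
            # the enhancer element exists regardless of links to tested genes
            # (it regulates some other gene), so peak selection is unbiased
            links.append(EnhancerLink("B", "1", e_start, e_end, f"{pid}_anchor", 0.9))
            n_sig = int(rng.integers(0, 4))
            for g in range(3):
                sig = g < n_sig
                rows.append(
                    {"peak_id": pid, "gene_id": f"{pid}_g{g}", "study_id": "s",
                     "cell_type": "B", "pp_h4": 0.95 if sig else 0.2, "significant": sig}
                )
                if rng.random() < (p_sig if sig else p_nonsig):
                    links.append(EnhancerLink("B", "1", e_start, e_end, f"{pid}_g{g}", 0.9))
        return leads, pd.DataFrame(rows), links

    def test_recovers_link_probabilities(self):
        leads, m, links = self._generate()
        out = enhancer_link_rates(leads, m, links)
        t = out["table"]
        sig_rate = np.average(
            t[t["significant"] == 1]["proportion_linked"],
            weights=t[t["significant"] == 1]["n_tests"],
        )
        nonsig_rate = np.average(
            t[t["significant"] == 0]["proportion_linked"],
            weights=t[t["significant"] == 0]["n_tests"],
        )
        assert sig_rate == pytest.approx(0.4, abs=0.07)
        assert nonsig_rate == pytest.approx(0.03, abs=0.07)
        assert out["model"]["coef"]["significant"] > 0

    def test_half_open_interval_excludes_end(self):
        m = matrix_from_counts([1])
        # lead at 1-based 201 = 0-based 200; interval [100, 200) misses it
        leads = {"pk0": ("1", 201)}
        links = [EnhancerLink("B", "1", 100, 200, "pk0_g0", 0.9)]
        out = enhancer_link_rates(leads, m, links)
        assert out["n_peaks"] == 0

    def test_impossible_score_threshold_empty(self):
        leads, m, links = self._generate(n_peaks=10)
        with pytest.warns(UserWarning):
            out = enhancer_link_rates(leads, m, links, score_min=1.0)
        assert out["table"].empty
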