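"""Expression-matrix plumbing: aggregation, filtering, scaling, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c4evo.expression import (
    ExpressionMatrix,
    aggregate_fpkm_by_gene,
    annotation_consistency,
    filter_expressed,
    intersect_modified_genes,
    pathway_enrichment,
    quantile_normalize,
    rank_conserved_scaling,
)
from c4evo.simulate import SyntheticScenario, simulate_expression


def meta_for(samples, species=None):
    species = species or {s: s for s in samples}
    return pd.DataFrame(
        {"species": [species[s] for s in samples]}, index=pd.Index(samples, name="sample")
    )


class TestAggregate:
    def test_contigs_summed_onto_gene(self):
        contigs = pd.DataFrame({"s1": [2.0, 3.5]}, index=["c1", "c2"])
        ann = pd.DataFrame({"contig": ["c1", "c2"], "gene": ["g1", "g1"], "evalue": [1e-10, 1e-5]})
        m = aggregate_fpkm_by_gene(contigs, ann, meta_for(["s1"]))
        assert m.values.loc["g1", "s1"] == pytest.approx(5.5)

    def test_single_contig_identity(self):
        contigs = pd.DataFrame({"s1": [4.2]}, index=["c1"])
        ann = pd.DataFrame({"contig": ["c1"], "gene": ["g1"], "evalue": [1e-9]})
        m = aggregate_fpkm_by_gene(contigs, ann, meta_for(["s1"]))
        assert m.values.loc["g1", "s1"] == pytest.approx(4.2)

    def test_evalue_threshold_applied(self):
        contigs = pd.DataFrame({"s1": [1.0, 1.0]}, index=["c1", "c2"])
        ann = pd.DataFrame({"contig": ["c1", "c2"], "gene": ["g1", "g1"], "evalue": [1e-9, 0.5]})
        m = aggregate_fpkm_by_gene(contigs, ann, meta_for(["s1"]))
        assert m.values.loc["g1", "s1"] == pytest.approx(1.0)

    def test_all_unannotated_empty_with_warning(self):
        contigs = pd.DataFrame({"s1": [1.0]}, index=["c1"])
        ann = pd.DataFrame({"contig": [], "gene": [], "evalue": []})
        with pytest.warns(UserWarning):
            m = aggregate_fpkm_by_gene(contigs, ann, meta_for(["s1"]))
        assert m.values.empty


class TestFilterExpressed:
    def make(self, rows):
        vals = pd.DataFrame(rows, columns=["s1", "s2"])
        vals.index = [f"g{i}" for i in range(len(vals))]
        return ExpressionMatrix(vals, meta_for(["s1", "s2"]))

    def test_boundary_kept_and_below_dropped(self):
        m = filter_expressed(self.make([[0.9, 0.5], [1.0, 0.0], [0.0, 0.0], [5.0, 2.0]]))
        assert list(m.values.index) == ["g1", "g3"]

    def test_species_level_max(self):
        # two samples of one species: gene passes if either sample reaches 1
        vals = pd.DataFrame({"a1": [0.6], "a2": [1.2]}, index=["g0"])
        m = ExpressionMatrix(vals, meta_for(["a1", "a2"], {"a1": "A", "a2": "A"}))
        assert len(filter_expressed(m).values) == 1


class TestQuantileNormalize:
    def test_worked_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 6.0, 8.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [2.5, 4.0, 5.5]
        assert out["b"].tolist() == [2.5, 4.0, 5.5]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_columns_share_sorted_vector_exactly(self, rng):
        df = pd.DataFrame(rng.lognormal(size=(50, 6)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out.columns:
            assert np.array_equal(np.sort(out[col].to_numpy()), ref)

    def test_ties_get_mean_quantile(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]


class TestRankConservedScaling:
    def synthetic(self, seed=0, n_genes=400, n_samples=6, factor_sigma=0.3):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 2, size=n_genes)
        factors = rng.lognormal(0, factor_sigma, size=n_samples)
        noise = rng.lognormal(0, 0.05, size=(n_genes, n_samples))
        vals = pd.DataFrame(
            base[:, None] * noise * factors[None, :],
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return ExpressionMatrix(vals, meta_for(list(vals.columns))), factors

    def test_identical_samples_fixed_point(self):
        vals = pd.DataFrame(
            {"s1": np.arange(1.0, 101.0), "s2": np.arange(1.0, 101.0)},
            index=[f"g{i}" for i in range(100)],
        )
        m = ExpressionMatrix(vals, meta_for(["s1", "s2"]))
        out = rank_conserved_scaling(m, n_ref=20)
        assert np.allclose(out.values, vals)

    def test_global_factor_removed(self):
        vals = pd.DataFrame(
            {"s1": np.arange(1.0, 101.0), "s2": 2.0 * np.arange(1.0, 101.0)},
            index=[f"g{i}" for i in range(100)],
        )
        m = ExpressionMatrix(vals, meta_for(["s1", "s2"]))
        out = rank_conserved_scaling(m, n_ref=20)
        assert np.allclose(out.values["s1"], out.values["s2"])

    def test_known_factors_recovered(self):
        m, factors = self.synthetic()
        out = rank_conserved_scaling(m, n_ref=100)
        applied = (m.values / out.values).median(axis=0).to_numpy()
        est = applied / np.exp(np.log(applied).mean())
        true = factors / np.exp(np.log(factors).mean())
        assert np.max(np.abs(est / true - 1)) < 0.05

    def test_rescaling_refused(self):
        m, _ = self.synthetic()
        out = rank_conserved_scaling(m, n_ref=100)
        with pytest.raises(ValueError, match="already"):
            rank_conserved_scaling(out, n_ref=100)

    def test_too_few_eligible_errors(self):
        m, _ = self.synthetic(n_genes=30)
        with pytest.raises(ValueError, match="n_ref"):
            rank_conserved_scaling(m, n_ref=1000)


class TestModifiedGenes:
    def test_intersection_sorted(self):
        assert intersect_modified_genes(["c", "a", "b"], ["b", "d", "c"]) == ["b", "c"]

    def test_disjoint_empty(self):
        assert intersect_modified_genes(["a"], ["b"]) == []


class TestPathwayEnrichment:
    def test_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        modified = universe[5:15]
        df = pathway_enrichment(modified, {"set": gene_set}, universe)
        overlap = 5
        # independent oracle: sum the hypergeometric tail directly
        want = sum(
            stats.hypergeom.pmf(k, 100, 10, 10) for k in range(overlap, 11)
        )
        assert df.loc["set", "p_value"] == pytest.approx(want, abs=1e-12)
        assert df.loc["set", "overlap"] == overlap

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        df = pathway_enrichment(universe[:5], {"set": universe[10:15]}, universe)
        assert df.loc["set", "p_value"] == pytest.approx(1.0)

    def test_degenerate_full_table(self):
        universe = [f"g{i}" for i in range(10)]
        df = pathway_enrichment(universe, {"set": universe}, universe)
        assert df.loc["set", "p_value"] == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            pathway_enrichment(["a"], {"s": ["a"]}, [])

    def test_bh_monotone(self, rng):
        universe = [f"g{i}" for i in range(200)]
        modified = list(rng.choice(universe, 30, replace=False))
        sets = {
            f"s{i}": list(rng.choice(universe, 20, replace=False)) for i in range(8)
        }
        df = pathway_enrichment(modified, sets, universe)
        by_raw = df.sort_values("p_value")
        assert by_raw["p_adjusted"].is_monotonic_increasing


class TestAnnotationConsistency:
    def test_all_members_match_arabidopsis(self):
        pct = annotation_consistency(["AT4G15530"] * 29, ["AT4G15530"])
        assert pct == pytest.approx(100.0)

    def test_majority_rule_without_arabidopsis(self):
        assert annotation_consistency(["A", "A", "A", "B"]) == pytest.approx(75.0)

    def test_partial_match(self):
        pct = annotation_consistency(["A", "A", "B"], ["A"])
        assert pct == pytest.approx(200.0 / 3)

    def test_bounds(self, rng):
        labels = [str(x) for x in rng.integers(0, 5, size=40)]
        pct = annotation_consistency(labels)
        assert 0.0 <= pct <= 100.0


class TestSimulatedMatrixRoundtrip:
    def test_fold_recovered_after_scaling(self, ftree):
        """Species-mean C4/C3 ratio of DE genes ≈ the injected fold change."""
        sc = SyntheticScenario(seed=9, n_genes_expression=3000, n_de_genes=60)
        values, metadata, truth = simulate_expression(sc, ftree)
        m = filter_expressed(ExpressionMatrix(values, metadata))
        out = rank_conserved_scaling(m, n_ref=300)
        species = metadata.loc[out.values.columns, "species"]
        sp_mean = out.values.T.groupby(species.values).mean().T
        c4 = ["F_bidentis", "F_kochiana", "F_trinervia", "F_australasica"]
        c3 = ["F_robusta", "F_cronquistii"]
        de = [g for g in truth["de_genes"] if g in sp_mean.index]
        ratio = sp_mean.loc[de, c4].mean(axis=1) / sp_mean.loc[de, c3].mean(axis=1)
        assert np.median(ratio) == pytest.approx(sc.fold_change, rel=0.2)
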