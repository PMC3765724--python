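"""Synthetic-experiment generator: catalogs, truth, arrays, traces."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import polytome as pt
from polytome.simulate import EMPTY_GENE_ID, _STOP_CODONS


class TestGenerateCatalog:
    def test_unique_ids_and_valid_lengths(self):
        cat = pt.generate_catalog(1948, seed=1)
        assert len(cat) == 1948
        assert cat.table["gene_id"].is_unique
        assert cat.table["cds_length"].between(90, 6000).all()
        assert (cat.table["cds_length"] % 3 == 0).all()

    def test_sequences_are_valid_cds(self):
        cat = pt.generate_catalog(30, seed=3)
        for row in cat.table.itertuples():
            assert len(row.cds_sequence) == row.cds_length
            assert row.cds_sequence.startswith("ATG")
            assert row.cds_sequence[-3:] in _STOP_CODONS
            # no premature stop
            inner = [
                row.cds_sequence[i : i + 3]
                for i in range(3, len(row.cds_sequence) - 3, 3)
            ]
            assert not any(c in _STOP_CODONS for c in inner)

    def test_seeded_determinism(self):
        a = pt.generate_catalog(10, seed=7)
        b = pt.generate_catalog(10, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_degenerate_weights(self):
        cat = pt.generate_catalog(15, category_weights={"prophage": 1.0}, seed=2)
        assert (cat.table["category"] == "prophage").all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pt.generate_catalog(9)


class TestConditionParams:
    def test_defaults_reflect_study_design(self, conditions):
        optimal, stress = conditions
        assert stress.n_fractions == 5 and optimal.n_fractions == 7
        assert stress.growth_rate == 0.05 and optimal.growth_rate == 0.88
        np.testing.assert_allclose(
            stress.ribosome_means, [0.0, 1.0, 2.1, 3.9, 8.4]
        )

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            pt.ConditionParams(
                "x", 0.5, 2, 5.0, ((1.0, 1, 1), (2.0, 2, 2))
            )  # S1 not 0
        with pytest.raises(ValueError):
            pt.ConditionParams(
                "x", 0.5, 3, 5.0, ((0.0, 0, 0), (2.0, 2, 2), (1.0, 1, 1))
            )  # not monotone


class TestGenerateTruth:
    def test_loading_distributions_sum_to_one(self, small_truth):
        for arr in small_truth.loading.values():
            np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-9)
            assert (arr >= 0).all()

    def test_occupancy_is_complement_of_s1(self, small_truth):
        for cond, arr in small_truth.loading.items():
            occ = small_truth.condition_table(cond)["occupancy_true"]
            np.testing.assert_allclose(occ.to_numpy(), 1 - arr[:, 0], atol=1e-12)

    def test_forced_down_archetype_moves_peak_lighter(self, small_catalog, conditions):
        optimal, stress = conditions
        truth = pt.generate_truth(
            small_catalog, optimal, stress,
            archetype_probs={"down": 1.0}, seed=5, frac_silent=0.0,
        )
        po = truth.condition_table("optimal")["peak_index"]
        ps = truth.condition_table("stress")["peak_index"]
        ribo_o = optimal.ribosome_means[po.to_numpy()]
        ribo_s = stress.ribosome_means[ps.to_numpy()]
        assert (ribo_s < ribo_o).all()
        # occupancy stays in the similarity band
        occ_o = truth.condition_table("optimal")["occupancy_true"]
        occ_s = truth.condition_table("stress")["occupancy_true"]
        small = (occ_s - occ_o).abs() <= 0.02
        assert small.mean() > 0.9  # all but the rare both-lower genes

    def test_antagonistic_raises_occupancy(self, small_catalog, conditions):
        optimal, stress = conditions
        truth = pt.generate_truth(
            small_catalog, optimal, stress,
            archetype_probs={"antagonistic": 1.0}, seed=5, frac_silent=0.0,
        )
        occ_o = truth.condition_table("optimal")["occupancy_true"].to_numpy()
        occ_s = truth.condition_table("stress")["occupancy_true"].to_numpy()
        assert (occ_s > occ_o).all()

    def test_archetype_counts_within_binomial_bounds(self, conditions):
        optimal, stress = conditions
        cat = pt.generate_catalog(1948, seed=1, with_sequences=False)
        truth = pt.generate_truth(cat, optimal, stress, seed=2)
        counts = truth.genes["archetype"].value_counts()
        n = len(cat)
        for arch, p in pt.simulate.DEFAULT_ARCHETYPE_PROBS.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts.get(arch, 0) <= hi

    def test_half_life_population_means(self, conditions):
        optimal, stress = conditions
        cat = pt.generate_catalog(4000, seed=3, with_sequences=False)
        truth = pt.generate_truth(cat, optimal, stress, seed=4)
        hl_o = truth.condition_table("optimal")["half_life_min"].mean()
        hl_s = truth.condition_table("stress")["half_life_min"].mean()
        assert hl_o == pytest.approx(6.2, rel=0.05)
        assert hl_s == pytest.approx(12.1, rel=0.05)

    def test_bad_probabilities_rejected(self, small_catalog, conditions):
        optimal, stress = conditions
        with pytest.raises(ValueError):
            pt.generate_truth(
                small_catalog, optimal, stress,
                archetype_probs={"up": 0.6, "down": 0.6},
            )

    def test_seeded_determinism(self, small_catalog, conditions):
        optimal, stress = conditions
        a = pt.generate_truth(small_catalog, optimal, stress, seed=9)
        b = pt.generate_truth(small_catalog, optimal, stress, seed=9)
        pd.testing.assert_frame_equal(a.per_condition, b.per_condition)
        for cond in a.loading:
            np.testing.assert_array_equal(a.loading[cond], b.loading[cond])


class TestSimulateArrays:
    def test_table_count_matches_design(self, small_truth):
        tables = pt.simulate_arrays(small_truth, pt.NoiseModel(seed=1), 5)
        stress = [t for t in tables if t.condition == "stress"]
        # five series of six arrays (S0..S5) under stress
        assert len(stress) == 30
        optimal = [t for t in tables if t.condition == "optimal"]
        assert len(optimal) == 5 * 8

    def test_zero_noise_duplicates_identical_and_proportional(self, small_truth):
        tables = pt.simulate_arrays(small_truth, pt.NoiseModel.noiseless(), 2)
        t = next(
            x for x in tables if x.condition == "stress" and x.fraction_id == "S3"
        )
        spots = t.spots[t.spots["gene_id"] != EMPTY_GENE_ID]
        by_gene = spots.groupby("gene_id")["intensity"]
        assert (by_gene.nunique() == 1).all()
        # background-corrected signal proportional to planted mRNA mass
        values = by_gene.first() - t.spots["background"].iloc[0]
        lf = small_truth.loading_frame("stress")["S3"]
        mrna = small_truth.condition_table("stress")["mrna_level"]
        expected = (lf * mrna).loc[values.index]
        mask = expected > 0
        ratio = values[mask] / expected[mask]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_every_gene_spotted_twice_with_empties(self, zero_noise_tables):
        t = zero_noise_tables[0]
        counts = t.spots[t.spots["gene_id"] != EMPTY_GENE_ID].groupby("gene_id").size()
        assert (counts == 2).all()
        assert (t.spots["gene_id"] == EMPTY_GENE_ID).sum() >= 50

    def test_seeded_determinism(self, small_truth):
        noise = pt.NoiseModel(seed=42)
        a = pt.simulate_arrays(small_truth, noise, 2)
        b = pt.simulate_arrays(small_truth, noise, 2)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.spots, tb.spots)

    def test_single_series_rejected(self, small_truth):
        with pytest.raises(ValueError):
            pt.simulate_arrays(small_truth, pt.NoiseModel(), 1)

    def test_tsv_round_trip(self, zero_noise_tables, tmp_path):
        t = zero_noise_tables[3]
        t.to_tsv(tmp_path / "t.tsv")
        back = pt.FractionIntensityTable.from_tsv(tmp_path / "t.tsv")
        assert back.condition == t.condition
        assert back.fraction_id == t.fraction_id
        assert back.rna_total == pytest.approx(t.rna_total)
        pd.testing.assert_frame_equal(back.spots, t.spots)


class TestSimulateTrace:
    @pytest.mark.parametrize("target", [0.59, 0.5, 0.61])
    def test_area_integration_recovers_target(self, small_truth, conditions, target):
        optimal, stress = conditions
        trace = pt.simulate_trace(small_truth, stress, target)
        engaged = pt.fraction_engaged_from_trace(trace)
        assert engaged == pytest.approx(100 * target, abs=1.0)

    def test_without_truth_equal_peaks(self, conditions):
        _, stress = conditions
        trace = pt.simulate_trace(None, stress, 0.5)
        assert pt.fraction_engaged_from_trace(trace) == pytest.approx(50.0, abs=1.0)

    def test_invalid_target_rejected(self, small_truth, conditions):
        _, stress = conditions
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pt.simulate_trace(small_truth, stress, bad)


class TestRatioArchetypes:
    def test_reference_column_and_labels(self):
        table, labels = pt.generate_ratio_archetypes(60, sigma=0.1, seed=1)
        assert (table["reference"] == 1.0).all()
        assert len(np.unique(labels)) == 6
        assert (table[list(table.columns[1:])] >= 0).to_numpy().all()

    def test_zero_sigma_is_exact_centers(self):
        table, labels = pt.generate_ratio_archetypes(12, sigma=0.0, seed=1)
        centers = np.asarray(pt.simulate.RATIO_ARCHETYPE_CENTERS)
        got = table[["k_trans", "k_deg", "mu", "density", "occupancy"]].to_numpy()
        np.testing.assert_allclose(got, centers[labels])
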