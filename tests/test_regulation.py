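"""Rate-constant decomposition, ratio table and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import polytome as pt


class TestDegradationRate:
    def test_unit_half_life(self):
        assert pt.degradation_rate(np.log(2)) == pytest.approx(1.0)

    def test_printed_optimal_mean_half_life(self):
        # the 6.2-minute average half-life under optimal growth
        assert pt.degradation_rate(6.2) == pytest.approx(0.1118, abs=5e-5)

    def test_ratio_is_inverse_half_life_ratio(self):
        ratio = pt.degradation_rate(12.1) / pt.degradation_rate(6.2)
        assert ratio == pytest.approx(6.2 / 12.1, rel=1e-12)
        assert ratio == pytest.approx(0.512, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pt.degradation_rate(0.0)


class TestTranscriptionRateConstant:
    def test_direct_substitution(self):
        assert pt.transcription_rate_constant(1.0, 0.1, 0.05, 1) == pytest.approx(0.15)

    def test_zero_mrna(self):
        assert pt.transcription_rate_constant(0.0, 0.1, 0.05, 1) == 0.0

    def test_copies_linearity(self):
        one = pt.transcription_rate_constant(2.0, 0.1, 0.05, 1)
        two = pt.transcription_rate_constant(2.0, 0.1, 0.05, 2)
        assert two == pytest.approx(one / 2)

    def test_invalid_copies(self):
        with pytest.raises(ValueError):
            pt.transcription_rate_constant(1.0, 0.1, 0.05, 0)

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(0.01, 100.0),
        st.floats(0.1, 100.0),
        st.floats(0.001, 2.0),
        st.integers(1, 5),
    )
    def test_steady_state_identity(self, mrna, t_half, mu_h, copies):
        """k_trans * copies == (k_deg + mu) * [mRNA], unit-harmonized."""
        rates = pt.rate_constants(
            pd.DataFrame(
                {
                    "gene_id": ["g"],
                    "half_life_min": [t_half],
                    "mrna_level": [mrna],
                    "gene_copies": [copies],
                }
            ),
            growth_rate_h=mu_h,
        )
        row = rates.iloc[0]
        lhs = row["k_trans"] * copies
        rhs = (row["k_deg"] + mu_h / 60.0) * mrna
        assert abs(lhs - rhs) <= 1e-9 * max(1.0, abs(rhs))


class TestBuildRatioTable:
    @staticmethod
    def _rates(genes, hl, mrna):
        return pd.DataFrame(
            {"gene_id": genes, "half_life_min": hl, "mrna_level": mrna}
        )

    @staticmethod
    def _trans(genes, dens, occ):
        return pd.DataFrame(
            {"density": dens, "occupancy": occ}, index=pd.Index(genes, name="gene_id")
        )

    def test_identical_conditions_all_ratios_one(self):
        genes = ["a", "b"]
        rates = pt.rate_constants(self._rates(genes, [5.0, 8.0], [1.0, 2.0]), 0.5)
        trans = self._trans(genes, [1.0, 2.0], [0.6, 0.7])
        table, excluded = pt.build_ratio_table(rates, rates, trans, trans)
        assert len(excluded) == 0
        np.testing.assert_allclose(table.to_numpy(), 1.0)

    def test_mu_ratio_constant_across_genes(self):
        genes = ["a", "b", "c"]
        rs = pt.rate_constants(self._rates(genes, [12.0, 9.0, 15.0], [1, 2, 3]), 0.05)
        ro = pt.rate_constants(self._rates(genes, [6.0, 7.0, 5.0], [2, 2, 4]), 0.88)
        trans = self._trans(genes, [1.0, 2.0, 0.5], [0.7, 0.8, 0.6])
        table, _ = pt.build_ratio_table(rs, ro, trans, trans)
        np.testing.assert_allclose(table["mu"], 0.05 / 0.88)
        assert (table["reference"] == 1.0).all()

    def test_kdeg_ratio_equals_inverse_half_life_ratio(self):
        genes = ["a"]
        rs = pt.rate_constants(self._rates(genes, [12.1], [1.0]), 0.05)
        ro = pt.rate_constants(self._rates(genes, [6.2], [1.0]), 0.88)
        trans = self._trans(genes, [1.0], [0.7])
        table, _ = pt.build_ratio_table(rs, ro, trans, trans)
        assert table.loc["a", "k_deg"] == pytest.approx(6.2 / 12.1, rel=1e-12)

    def test_incomplete_genes_excluded_with_reason(self):
        rs = pt.rate_constants(self._rates(["a", "b"], [5, 5], [1, 1]), 0.05)
        ro = pt.rate_constants(self._rates(["a"], [5], [1]), 0.88)
        trans = self._trans(["a", "b"], [1.0, 1.0], [0.7, 0.7])
        table, excluded = pt.build_ratio_table(rs, ro, trans, trans)
        assert list(table.index) == ["a"]
        assert excluded.iloc[0]["gene_id"] == "b"
        assert "rates_optimal" in excluded.iloc[0]["reason"]


class TestClusterPatterns:
    def test_exact_recovery_at_zero_noise(self):
        table, labels = pt.generate_ratio_archetypes(120, sigma=0.0, seed=0)
        res = pt.cluster_patterns(table.set_index("gene_id"), k=6)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_two_separated_archetypes(self):
        centers = [(0.2, 0.2, 0.05, 0.2, 0.9), (2.5, 2.0, 0.05, 2.8, 1.2)]
        table, labels = pt.generate_ratio_archetypes(
            40, sigma=0.05, seed=2, centers=centers
        )
        res = pt.cluster_patterns(table.set_index("gene_id"), k=2)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_row_permutation_invariance(self):
        table, labels = pt.generate_ratio_archetypes(60, sigma=0.1, seed=3)
        t = table.set_index("gene_id")
        res = pt.cluster_patterns(t, k=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(t))
        res_p = pt.cluster_patterns(t.iloc[perm], k=6)
        assert (
            adjusted_rand_score(
                res.labels.loc[t.index], res_p.labels.loc[t.index]
            )
            == 1.0
        )

    def test_labels_sorted_by_decreasing_size(self):
        table, _ = pt.generate_ratio_archetypes(63, sigma=0.05, seed=4)
        res = pt.cluster_patterns(table.set_index("gene_id"), k=6)
        sizes = res.labels.value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_degenerate_identical_genes_flagged(self):
        t = pd.DataFrame(
            np.ones((10, 6)),
            columns=list(pt.simulate.RATIO_COLUMNS),
            index=[f"g{i}" for i in range(10)],
        )
        res = pt.cluster_patterns(t, k=6)
        assert res.k < 6  # cannot split identical points into 6 real clusters

    def test_k_larger_than_n_rejected(self):
        table, _ = pt.generate_ratio_archetypes(6, sigma=0.0, seed=0)
        with pytest.raises(ValueError):
            pt.cluster_patterns(table.set_index("gene_id"), k=7)


class TestRegulationModel:
    def test_end_to_end_summary(self, small_truth, zero_noise_results):
        rates = {
            name: small_truth.condition_table(name)
            .reset_index()[["gene_id", "half_life_min", "mrna_level"]]
            .query("mrna_level > 0")
            for name in ("stress", "optimal")
        }
        model = pt.RegulationModel(
            rates["stress"],
            rates["optimal"],
            0.05,
            0.88,
            zero_noise_results["stress"],
            zero_noise_results["optimal"],
        )
        res = model.fit(k=4)
        assert set(res.ratios.columns) == set(pt.simulate.RATIO_COLUMNS)
        assert res.clusters.labels.isin(range(1, 5)).all()
        # steady-state identity holds for every gene and condition
        for frame, mu_h in ((res.rates_stress, 0.05), (res.rates_optimal, 0.88)):
            lhs = frame["k_trans"] * frame["gene_copies"]
            rhs = (frame["k_deg"] + mu_h / 60.0) * frame["mrna_level"]
            assert (lhs - rhs).abs().max() <= 1e-9
        assert "Ward clustering" in res.summary()
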