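"""TPM normalisation, correlation distances, clustering, habitat labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from streamline_scan import abundance_habitat as ah
from streamline_scan import synthetic_data as sd
from streamline_scan.io_formats import SampleMetadata

from oracles import naive_average_linkage, naive_cophenetic


def _df(rows, index=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    index = index or [f"G{i}" for i in range(rows.shape[0])]
    columns = columns or [f"S{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=index, columns=columns)


class TestComputeTPM:
    def test_single_genome_gets_the_whole_million(self):
        tpm = ah.compute_tpm(_df([[7]]), pd.Series({"G0": 1000.0}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_per_kb_rates_split_evenly(self):
        tpm = ah.compute_tpm(
            _df([[100], [300]]), pd.Series({"G0": 1000.0, "G1": 3000.0})
        )
        assert tpm["S0"].tolist() == pytest.approx([500_000, 500_000])

    def test_scale_invariance_per_sample(self):
        counts = _df([[3, 10], [5, 2]])
        lengths = pd.Series({"G0": 1500.0, "G1": 900.0})
        doubled = counts.copy()
        doubled["S0"] *= 2
        assert np.allclose(
            ah.compute_tpm(counts, lengths)["S0"],
            ah.compute_tpm(doubled, lengths)["S0"],
        )

    def test_all_zero_column_stays_zero(self):
        tpm = ah.compute_tpm(_df([[0, 5], [0, 5]]),
                             pd.Series({"G0": 1000.0, "G1": 1000.0}))
        assert (tpm["S0"] == 0).all()

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            ah.compute_tpm(_df([[1]]), pd.Series({"G0": 0.0}))

    @given(st.integers(min_value=0, max_value=10**8))
    def test_nonzero_columns_sum_to_a_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = _df(rng.integers(0, 50, size=(5, 4)))
        lengths = pd.Series(rng.uniform(500, 5000, size=5),
                            index=counts.index)
        tpm = ah.compute_tpm(counts, lengths)
        for col in tpm.columns:
            total = counts[col].sum()
            if total > 0:
                assert tpm[col].sum() == pytest.approx(1e6, rel=1e-6)
            else:
                assert (tpm[col] == 0).all()


class TestLogTransform:
    def test_zero_maps_to_zero_with_unit_pseudocount(self):
        assert ah.log_transform(_df([[0.0]])).iloc[0, 0] == 0.0

    def test_999_maps_to_three(self):
        assert ah.log_transform(_df([[999.0]])).iloc[0, 0] == pytest.approx(3.0)

    def test_monotone(self):
        out = ah.log_transform(_df([[1.0, 10.0, 100.0]]))
        assert out.iloc[0].is_monotonic_increasing

    def test_nonpositive_pseudocount_is_error(self):
        with pytest.raises(ValueError):
            ah.log_transform(_df([[1.0]]), pseudocount=0.0)


class TestCorrelationDistance:
    def test_identical_profiles_have_zero_distance(self):
        d = ah.correlation_distance(_df([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_profiles_have_distance_two(self):
        d = ah.correlation_distance(_df([[1, 2, 3], [3, 2, 1]]))
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_perfect_linear_scaling_has_zero_distance(self):
        d = ah.correlation_distance(_df([[1, 2, 3], [2, 4, 6]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_fewer_than_two_samples_is_error(self):
        with pytest.raises(ValueError):
            ah.correlation_distance(_df([[1], [2]]))

    def test_zero_variance_rows_get_missing_distances(self):
        d = ah.correlation_distance(_df([[5, 5, 5], [1, 2, 3], [1, 3, 2]]))
        assert d.loc["G0"].drop("G0").isna().all()
        assert np.isfinite(d.loc["G1", "G2"])

    @given(st.integers(min_value=0, max_value=10**8))
    def test_symmetry_range_and_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        d = ah.correlation_distance(_df(rng.normal(size=(6, 5))))
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all() and (arr <= 2).all()


def _random_distance(rng, n):
    a = rng.uniform(0.0, 2.0, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestClusterGenomes:
    def test_two_genomes_two_singletons(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        res = ah.cluster_genomes(d, k=2)
        assert res.groups["A"] != res.groups["B"]

    def test_two_well_separated_pairs_recovered(self):
        # hand-checkable 4x4: {A,B} at 0.1, {C,D} at 0.1, cross ~1.5
        ids = list("ABCD")
        d = pd.DataFrame(
            [[0.0, 0.1, 1.5, 1.4],
             [0.1, 0.0, 1.6, 1.5],
             [1.5, 1.6, 0.0, 0.1],
             [1.4, 1.5, 0.1, 0.0]], index=ids, columns=ids)
        res = ah.cluster_genomes(d, k=2)
        assert res.groups["A"] == res.groups["B"]
        assert res.groups["C"] == res.groups["D"]
        assert res.groups["A"] != res.groups["C"]

    def test_matches_naive_average_linkage_oracle(self, rng):
        from sklearn.metrics import adjusted_rand_score
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        for _ in range(100):
            d = _random_distance(rng, 8)
            ids = [f"G{i}" for i in range(8)]
            df = pd.DataFrame(d, index=ids, columns=ids)
            res = ah.cluster_genomes(df, k=2)
            oracle_labels, oracle_heights = naive_average_linkage(d, k=2)
            got = [res.groups[g] for g in ids]
            assert adjusted_rand_score(oracle_labels, got) == 1.0
            # full hierarchy agreement via cophenetic distances
            coph = squareform(cophenet(res.linkage_matrix))
            assert np.allclose(coph, naive_cophenetic(d), atol=1e-10)
            assert np.allclose(sorted(oracle_heights),
                               sorted(res.linkage_matrix[:, 2]), atol=1e-10)

    def test_more_groups_than_items_is_error(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.raises(ValueError):
            ah.cluster_genomes(d, k=3)

    def test_zero_variance_rows_excluded(self):
        logtpm = _df([[5, 5, 5], [1, 2, 3], [1, 3, 2], [3, 2, 1]])
        res = ah.cluster_genomes(ah.correlation_distance(logtpm), k=2)
        assert res.excluded == ["G0"]
        assert set(res.groups) == {"G1", "G2", "G3"}


class TestClusterSamples:
    def test_duplicated_sample_columns_merge_first(self, rng):
        base = rng.normal(size=6)
        logtpm = _df(
            np.column_stack([base, base, rng.normal(size=6), base + rng.normal(size=6)]),
        )
        res = ah.cluster_samples(logtpm)
        Z = res.linkage_matrix
        first = sorted(int(x) for x in Z[0, :2])
        assert [res.ids[i] for i in first] == ["S0", "S1"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_block_matrix_splits_samples_by_layer(self):
        m, samples, _ = sd.simulate_abundance(
            sd.AbundanceSimSpec(seed=5, depth_effect=100.0)
        )
        logtpm = ah.log_transform(ah.compute_tpm(m.counts, m.lengths))
        res = ah.cluster_samples(logtpm)
        layer = {s.sample_id: s.depth_layer in ("SRF", "DCM") for s in samples}
        groups_of_epi = {res.groups[s] for s in res.ids if layer[s]}
        groups_of_mes = {res.groups[s] for s in res.ids if not layer[s]}
        assert len(groups_of_epi) == 1 and len(groups_of_mes) == 1
        assert groups_of_epi != groups_of_mes

    def test_column_permutation_does_not_change_topology(self, rng):
        logtpm = _df(rng.normal(size=(5, 6)))
        res1 = ah.cluster_samples(logtpm)
        perm = list(rng.permutation(logtpm.columns))
        res2 = ah.cluster_samples(logtpm[perm])
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform
        c1 = pd.DataFrame(squareform(cophenet(res1.linkage_matrix)),
                          index=res1.ids, columns=res1.ids)
        c2 = pd.DataFrame(squareform(cophenet(res2.linkage_matrix)),
                          index=res2.ids, columns=res2.ids)
        assert np.allclose(c1.loc[res1.ids, res1.ids], c2.loc[res1.ids, res1.ids])


class TestNewick:
    def test_newick_contains_all_leaves_and_parses(self):
        from io import StringIO
        from Bio import Phylo

        m, _, _ = sd.simulate_abundance(
            sd.AbundanceSimSpec(seed=6, n_epi_genomes=3, n_meso_genomes=3,
                                n_epi_samples=4, n_meso_samples=4)
        )
        logtpm = ah.log_transform(ah.compute_tpm(m.counts, m.lengths))
        res = ah.cluster_genomes(ah.correlation_distance(logtpm))
        tree = Phylo.read(StringIO(ah.to_newick(res)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(res.ids)


class TestAssignHabitat:
    def _setup(self, seed=7, depth_effect=100.0):
        m, samples, truth = sd.simulate_abundance(
            sd.AbundanceSimSpec(seed=seed, depth_effect=depth_effect)
        )
        logtpm = ah.log_transform(ah.compute_tpm(m.counts, m.lengths))
        clusters = ah.cluster_genomes(ah.correlation_distance(logtpm))
        return clusters, logtpm, samples, truth

    def test_strong_effect_recovers_truth_exactly(self):
        clusters, logtpm, samples, truth = self._setup()
        assignment = ah.assign_habitat(clusters, logtpm, samples)
        assert assignment.labels == truth.habitat_labels

    def test_label_equivariance_under_group_swap(self):
        clusters, logtpm, samples, _ = self._setup()
        assignment = ah.assign_habitat(clusters, logtpm, samples)
        swapped = ah.ClusterResult(
            clusters.ids, clusters.linkage_matrix,
            {g: 3 - grp for g, grp in clusters.groups.items()},
        )
        assignment2 = ah.assign_habitat(swapped, logtpm, samples)
        assert assignment2.labels == assignment.labels

    def test_null_effect_still_produces_labels(self):
        clusters, logtpm, samples, _ = self._setup(seed=8, depth_effect=1.0)
        assignment = ah.assign_habitat(clusters, logtpm, samples)
        assert set(assignment.labels.values()) <= {"epipelagic", "mesopelagic"}
        assert set(assignment.labels) == set(clusters.groups)

    def test_missing_depth_pool_is_error(self):
        clusters, logtpm, samples, _ = self._setup()
        srf_only = [s for s in samples if s.depth_layer in ("SRF", "DCM")]
        with pytest.raises(ValueError):
            ah.assign_habitat(clusters, logtpm[[s.sample_id for s in srf_only]],
                              srf_only)

    def test_omz_samples_do_not_vote(self):
        clusters, logtpm, samples, truth = self._setup(seed=9)
        # relabel one MES sample as OMZ: vote must use remaining MES only
        relabeled = [
            SampleMetadata(s.sample_id, "OMZ" if s.sample_id == samples[-1].sample_id
                           else s.depth_layer, s.region)
            for s in samples
        ]
        assignment = ah.assign_habitat(clusters, logtpm, relabeled)
        assert assignment.labels == truth.habitat_labels
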