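"""Subclone deconvolution: mode recovery, classification, partition and
stability properties, agreement with an EM binomial-mixture oracle."""

import numpy as np
import pandas as pd
import pytest

import clonedyn as cd
from clonedyn.errors import InputError

from _oracles import em_binomial_mixture_bic


def binomial_ccf_frame(centers, sizes, depth=150, seed=0, sample="s1"):
    """1-D CCF observations from binomial read sampling at purity 1, CN 2
    (ccf = 2 * vaf), with matching binomial variances."""
    rng = np.random.default_rng(seed)
    rows, var, alt_all, dep_all = [], [], [], []
    for center, size in zip(centers, sizes):
        p = center / 2
        dep = rng.poisson(depth, size).clip(min=1)
        alt = rng.binomial(dep, p)
        vaf = alt / dep
        rows.extend(2 * vaf)
        var.extend(4 * vaf * (1 - vaf) / dep)
        alt_all.extend(alt)
        dep_all.extend(dep)
    index = pd.MultiIndex.from_tuples(
        [("1", 1000 * (i + 1), "A", "T") for i in range(len(rows))],
        names=["chrom", "pos", "ref", "alt"],
    )
    ccf = pd.DataFrame({sample: rows}, index=index)
    variance = pd.DataFrame({sample: var}, index=index)
    return ccf, variance, np.array(alt_all), np.array(dep_all)


class TestDeconvolute:
    def test_single_tight_cluster(self):
        ccf, var, _, _ = binomial_ccf_frame([1.0], [80], seed=1)
        clusters = cd.deconvolute(ccf, var)
        assert len(clusters) == 1
        assert clusters[0].centers["s1"] == pytest.approx(1.0, abs=0.03)
        assert clusters[0].weight == 80

    def test_two_component_mixture_matches_truth_and_em_oracle(self):
        ccf, var, alt, dep = binomial_ccf_frame([1.0, 0.4], [150, 150], seed=2)
        clusters = cd.deconvolute(ccf, var)
        centers = sorted(c.centers["s1"] for c in clusters)
        assert len(clusters) == 2
        assert centers[0] == pytest.approx(0.4, abs=0.05)
        assert centers[1] == pytest.approx(1.0, abs=0.05)
        k, p, _ = em_binomial_mixture_bic(alt, dep)
        assert k == 2
        oracle_centers = sorted(2 * p)
        for ours, oracle in zip(centers, oracle_centers):
            assert ours == pytest.approx(min(oracle, 1.0), abs=0.05)

    @pytest.mark.parametrize("true_centers", [[0.9, 0.5], [0.8, 0.5, 0.2], [0.6]])
    def test_em_oracle_agreement_on_separated_components(self, true_centers):
        ccf, var, alt, dep = binomial_ccf_frame(
            true_centers, [120] * len(true_centers), seed=5
        )
        clusters = cd.deconvolute(ccf, var)
        k, p, _ = em_binomial_mixture_bic(alt, dep)
        assert len(clusters) == k == len(true_centers)
        ours = sorted(c.centers["s1"] for c in clusters)
        for a, b in zip(ours, sorted(np.minimum(2 * p, 1.0))):
            assert a == pytest.approx(b, abs=0.05)

    def test_partition_property(self):
        ccf, var, _, _ = binomial_ccf_frame([1.0, 0.4], [100, 100], seed=3)
        clusters = cd.deconvolute(ccf, var)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(set(members)) == 200
        assert sum(c.weight for c in clusters) == 200

    def test_input_order_stability(self):
        ccf, var, _, _ = binomial_ccf_frame([1.0, 0.4], [100, 100], seed=4)
        clusters = cd.deconvolute(ccf, var)
        perm = np.random.default_rng(0).permutation(len(ccf))
        clusters_p = cd.deconvolute(ccf.iloc[perm], var.iloc[perm])
        sets = sorted((frozenset(c.members) for c in clusters), key=sorted)
        sets_p = sorted((frozenset(c.members) for c in clusters_p), key=sorted)
        assert sets == sets_p

    def test_too_few_mutations_rejected(self):
        ccf, var, _, _ = binomial_ccf_frame([1.0], [3], seed=6)
        with pytest.raises(InputError):
            cd.deconvolute(ccf, var)

    def test_all_missing_rejected(self):
        ccf = pd.DataFrame({"s1": [np.nan] * 10})
        with pytest.raises(InputError):
            cd.deconvolute(ccf)

    def test_undersized_groups_dissolved(self):
        # 3 stray points midway cannot form their own cluster (min size 5)
        ccf, var, _, _ = binomial_ccf_frame([1.0, 0.1], [60, 3], depth=5000, seed=7)
        clusters = cd.deconvolute(ccf, var)
        assert len(clusters) == 1 or all(c.weight >= 5 for c in clusters)


class TestClassifyCluster:
    @pytest.mark.parametrize(
        "centers,expected,subclonal",
        [
            ({"a": 1.0, "b": 1.0, "c": 1.0}, "clonal_all", False),
            ({"a": 0.95, "b": 0.02}, "private:a", False),
            ({"a": 0.4, "b": 0.0, "c": 0.0}, "private:a", True),
            ({"a": 0.5, "b": 0.6}, "shared_subclonal", True),
            ({"a": 0.9, "b": 0.5}, "shared_subclonal", True),
            ({"a": 0.88, "b": 0.86}, "clonal_all", False),
        ],
    )
    def test_decision_table(self, centers, expected, subclonal):
        cl = cd.CCFCluster("X", centers, members=list(range(10)))
        assert cd.classify_cluster(cl) == expected
        assert cl.subclonal == subclonal

    def test_threshold_grid_consistency(self):
        """Enumerated decision table: exactly one label per center grid point."""
        for a in np.linspace(0, 1, 11):
            for b in np.linspace(0, 1, 11):
                cl = cd.CCFCluster("X", {"a": a, "b": b}, members=list(range(5)))
                label = cd.classify_cluster(cl)
                if a >= 0.85 and b >= 0.85:
                    assert label == "clonal_all"
                elif (a > 0.10) != (b > 0.10):
                    assert label.startswith("private:")
                else:
                    assert label == "shared_subclonal"


class TestPairwiseClusters:
    def test_three_population_scatter(self):
        rng = np.random.default_rng(8)

        def draw(center_a, center_b, n):
            dep = rng.poisson(150, (n, 2)).clip(min=1)
            alt = rng.binomial(dep, [center_a / 2, center_b / 2])
            return 2 * alt / dep, 4 * (alt / dep) * (1 - alt / dep) / dep

        blocks = [draw(1.0, 1.0, 200), draw(1.0, 0.0, 150), draw(0.0, 1.0, 180)]
        vals = np.vstack([b[0] for b in blocks])
        var = np.vstack([b[1] for b in blocks])
        index = pd.MultiIndex.from_tuples(
            [("1", 1000 * (i + 1), "A", "T") for i in range(len(vals))],
            names=["chrom", "pos", "ref", "alt"],
        )
        ccf = pd.DataFrame(vals, columns=["a", "b"], index=index)
        variance = pd.DataFrame(var, columns=["a", "b"], index=index)
        clusters, table = cd.pairwise_clusters(ccf, "a", "b", variance)
        labels = sorted(c.classification for c in clusters)
        assert labels == ["clonal_all", "private:a", "private:b"]
        assert set(table.columns) == {"ccf_a", "ccf_b", "cluster", "classification"}
        assert len(table) == 530 and table["cluster"].notna().all()

    def test_duplicated_sample_on_diagonal(self):
        ccf, var, _, _ = binomial_ccf_frame([1.0, 0.4], [100, 100], seed=9)
        ccf2 = pd.DataFrame({"a": ccf["s1"], "b": ccf["s1"]})
        var2 = pd.DataFrame({"a": var["s1"], "b": var["s1"]})
        clusters, _ = cd.pairwise_clusters(ccf2, "a", "b", var2)
        for c in clusters:
            assert c.centers["a"] == pytest.approx(c.centers["b"], abs=1e-9)

    def test_missing_sample_rejected(self):
        ccf = pd.DataFrame({"a": [1.0] * 10})
        with pytest.raises(InputError):
            cd.pairwise_clusters(ccf, "a", "zzz")

    def test_p04_marker_mutations_private_to_expected_lesions(
        self, p04_matrix
    ):
        """The T790M-like marker clusters private to the peritoneal biopsy,
        the V600E-like marker private to the liver lineage."""
        clusters, table = cd.pairwise_clusters(
            p04_matrix.ccf, "peritoneal", "liver1", p04_matrix.variance
        )
        genes = p04_matrix.gene.dropna()
        t790m_key = genes[genes == "EGFR_T790M"].index[0]
        v600e_key = genes[genes == "BRAF_V600E"].index[0]
        del19_key = genes[genes == "EGFR_del19"].index[0]
        assert table.loc[t790m_key, "classification"] == "private:peritoneal"
        assert table.loc[v600e_key, "classification"] == "private:liver1"
        assert table.loc[del19_key, "classification"] == "clonal_all"


class TestP04Peritoneal:
    def test_two_subclone_modes(self, p04_matrix):
        """Single-biopsy deconvolution of the peritoneal sample finds the
        clonal mode near 1.0 and the subclone near 0.4."""
        col = p04_matrix.raw[["peritoneal"]].dropna()
        var = p04_matrix.variance[["peritoneal"]].loc[col.index]
        clusters = cd.deconvolute(col, var)
        centers = sorted(c.centers["peritoneal"] for c in clusters)
        assert centers[0] == pytest.approx(0.0, abs=0.05)
        assert centers[-1] == pytest.approx(1.0, abs=0.05)
        assert any(abs(c - 0.4) < 0.05 for c in centers)
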