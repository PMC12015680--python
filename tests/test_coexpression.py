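"""Pearson screening, cis/trans labeling, network summary and export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncnet.coexpression import (
    coexpressed_pairs,
    label_cis_trans,
    network_summary,
    export_network,
    pearson_with_p,
)
from lncnet.expression import FpkmMatrix

PAIR_COLS = ["lncrna_id", "gene_id", "r", "p_value", "sign", "relation"]


def make_fpkm(arr, prefix, design=None):
    arr = np.asarray(arr, dtype=float)
    samples = [f"s{i}" for i in range(arr.shape[1])]
    if design is None:
        design = pd.Series(["TL"] * arr.shape[1], index=samples)
    return FpkmMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])], columns=samples),
        design,
    )


class TestPearsonWithP:
    def test_identity_gives_r_one_p_zero(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_known_value_at_threshold(self):
        """r = 0.6 at n = 24 corresponds to a two-sided p of about 0.0019."""
        # construct vectors with exactly r = 0.6
        n = 24
        rng = np.random.default_rng(2)
        x = rng.standard_normal(n)
        xc = x - x.mean()
        z = rng.standard_normal(n)
        z = z - z.mean()
        z -= np.dot(z, xc) / np.dot(xc, xc) * xc  # orthogonal to x, centered
        y = 0.6 * xc / np.linalg.norm(xc) + 0.8 * z / np.linalg.norm(z)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(0.00194, abs=5e-5)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x, y = rng.standard_normal((2, 15))
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_approximates_permutation_null(self):
        """t-based p tracks a permutation p to ~0.02 absolute (5 spot pairs).

        The randomization null conditions on the data and deviates from the
        unconditional t null by up to ~1e-2 at n = 24, so the comparison is
        an approximation check, not an exact-agreement check.
        """
        rng = np.random.default_rng(11)
        n, n_perm = 24, 10_000
        for _ in range(5):
            x, y = rng.standard_normal((2, n))
            r_obs, p_t = pearson_with_p(x, y)
            xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
            yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
            perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
            r_null = perms @ xc
            p_perm = (1 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12)) / (1 + n_perm)
            assert abs(p_t - p_perm) <= 0.02

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [2.0, 1.0])


class TestCoexpressedPairs:
    def test_duplicated_row_yields_r_one(self):
        rng = np.random.default_rng(1)
        lnc = make_fpkm(rng.exponential(5, size=(2, 10)), "L")
        mrna_arr = rng.exponential(5, size=(3, 10))
        mrna_arr[0] = lnc.fpkm.iloc[0]
        mrna = make_fpkm(mrna_arr, "G")
        pairs = coexpressed_pairs(lnc, mrna)
        hit = pairs[(pairs.lncrna_id == "L0") & (pairs.gene_id == "G0")]
        assert len(hit) == 1 and hit.iloc[0].r == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        """20 x 50 random matrix: pair set equals the per-pair oracle."""
        rng = np.random.default_rng(13)
        lnc = make_fpkm(rng.exponential(2, size=(20, 12)), "L")
        mrna = make_fpkm(rng.exponential(2, size=(50, 12)), "G")
        r_thr, p_thr = 0.45, 0.05
        pairs = coexpressed_pairs(lnc, mrna, r_thr, p_thr)
        got = set(zip(pairs.lncrna_id, pairs.gene_id))
        expected = set()
        for li in lnc.genes:
            for gi in mrna.genes:
                x = np.log2(lnc.fpkm.loc[li].to_numpy() + 1)
                y = np.log2(mrna.fpkm.loc[gi].to_numpy() + 1)
                r, p = pearson_with_p(x, y)
                if abs(r) > r_thr and p <= p_thr:
                    expected.add((li, gi))
        assert got == expected

    def test_r_threshold_is_a_strict_inequality(self):
        """|r| must strictly exceed the threshold: at 1.0 nothing survives."""
        rng = np.random.default_rng(14)
        lnc = make_fpkm(rng.exponential(2, size=(3, 8)), "L")
        mrna_arr = rng.exponential(2, size=(3, 8))
        # exactly collinear with L2 in log2(FPKM+1) space: r = 1
        mrna_arr[1] = 2.0 * (lnc.fpkm.iloc[2].to_numpy() + 1) - 1
        mrna = make_fpkm(mrna_arr, "G")
        assert len(coexpressed_pairs(lnc, mrna, r_threshold=1.0, p_threshold=1.0)) == 0
        at_09 = coexpressed_pairs(lnc, mrna, r_threshold=0.9, p_threshold=1.0)
        assert ("L2", "G1") in set(zip(at_09.lncrna_id, at_09.gene_id))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(15)
        lnc = make_fpkm(rng.exponential(2, size=(10, 10)), "L")
        mrna = make_fpkm(rng.exponential(2, size=(30, 10)), "G")

        def pair_set(r_thr, p_thr):
            p = coexpressed_pairs(lnc, mrna, r_thr, p_thr)
            return set(zip(p.lncrna_id, p.gene_id))

        assert pair_set(0.6, 0.05) <= pair_set(0.4, 0.05)
        assert pair_set(0.4, 0.01) <= pair_set(0.4, 0.05)

    def test_mismatched_samples_rejected(self):
        lnc = make_fpkm(np.ones((2, 5)) + np.arange(5), "L")
        mrna = make_fpkm(np.ones((2, 4)) + np.arange(4), "G")
        with pytest.raises(ValueError):
            coexpressed_pairs(lnc, mrna)


class TestCisTransAndSummary:
    def example_pairs(self):
        return pd.DataFrame(
            [
                ("L1", "G1", 0.7, 0.001, "positive", ""),
                ("L1", "G2", -0.8, 0.001, "negative", ""),
                ("L2", "G1", 0.9, 0.0001, "positive", ""),
            ],
            columns=PAIR_COLS,
        )

    def test_labels_follow_colocation_set(self):
        labeled = label_cis_trans(self.example_pairs(), {("L1", "G1")})
        assert labeled.relation.tolist() == ["cis", "trans", "trans"]

    def test_summary_hand_count(self):
        s = network_summary(self.example_pairs())
        assert (s.all_pairs, s.all_lncrna, s.all_gene) == (3, 2, 2)
        assert (s.positive_pairs, s.negative_pairs) == (2, 1)
        assert s.positive_pairs + s.negative_pairs == s.all_pairs

    def test_summary_empty(self):
        s = network_summary(pd.DataFrame(columns=PAIR_COLS))
        assert s.all_pairs == 0 and s.positive_lncrna == 0

    def test_summary_conservation_on_random_pairs(self):
        rng = np.random.default_rng(16)
        rows = [
            (f"L{rng.integers(5)}", f"G{rng.integers(9)}", r, 0.001,
             "positive" if r > 0 else "negative", "")
            for r in rng.uniform(-1, 1, size=60)
        ]
        s = network_summary(pd.DataFrame(rows, columns=PAIR_COLS).drop_duplicates(["lncrna_id", "gene_id"]))
        assert s.positive_pairs + s.negative_pairs == s.all_pairs
        assert s.positive_lncrna <= s.all_lncrna and s.negative_gene <= s.all_gene


class TestExportNetwork:
    def test_three_pair_network_counts(self, tmp_path):
        pairs = label_cis_trans(TestCisTransAndSummary().example_pairs(), {("L1", "G1")})
        g = export_network(pairs, tmp_path / "n.graphml", tmp_path / "n.sif")
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_empty_network_is_valid(self, tmp_path):
        import networkx as nx

        pairs = pd.DataFrame(columns=PAIR_COLS)
        export_network(pairs, tmp_path / "e.graphml", tmp_path / "e.sif")
        back = nx.read_graphml(tmp_path / "e.graphml")
        assert back.number_of_nodes() == 0

    def test_re_export_is_byte_identical(self, tmp_path):
        pairs = label_cis_trans(TestCisTransAndSummary().example_pairs(), set())
        paths = [(tmp_path / f"a{i}.graphml", tmp_path / f"a{i}.sif") for i in range(2)]
        for gp, sp in paths:
            export_network(pairs, gp, sp)
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()


class TestPlantedPairRecovery:
    def test_sensitivity_and_false_rate(self, dataset, annotation):
        """Planted latent-factor pairs recovered at >=0.9; non-pairs pass <=0.01."""
        import os
        import lncnet as ln

        truth = dataset["truth"]
        cm = ln.CountMatrix.from_tsv(
            os.path.join(dataset["dir"], "counts.tsv"),
            os.path.join(dataset["dir"], "design.tsv"),
        )
        fpkm = ln.filter_expressed(ln.compute_fpkm(cm, annotation))
        lnc = [g for g in fpkm.genes if annotation[g].biotype == "lncRNA"]
        mrna = [g for g in fpkm.genes if annotation[g].biotype == "protein_coding"]
        pairs = coexpressed_pairs(fpkm.subset(lnc), fpkm.subset(mrna))
        found = set(zip(pairs.lncrna_id, pairs.gene_id))
        planted = truth.pair_set()
        sensitivity = len(found & planted) / len(planted)
        false_rate = len(found - planted) / (len(lnc) * len(mrna) - len(planted))
        assert sensitivity >= 0.9
        assert false_rate <= 0.01
        labeled = label_cis_trans(pairs, truth.colocated)
        cis_found = set(
            map(tuple, labeled.loc[labeled.relation == "cis", ["lncrna_id", "gene_id"]].values)
        )
        assert cis_found == {p for p in found if p in truth.colocated}
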