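"""Size factors, the NB Wald test, and DEG calling at the study thresholds."""

import numpy as np
import pandas as pd
import pytest

from lncnet.de import (
    call_degs,
    de_contrast,
    deg_count_table,
    deg_sets,
    nb_test,
    parse_contrast,
    size_factors,
)
from lncnet.expression import CountMatrix

UNIT = np.ones(6)


def make_cm(arr, groups):
    samples = [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples),
        pd.Series(groups, index=samples),
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        arr = np.tile([[10], [20], [5]], (1, 4))
        cm = make_cm(arr, ["TL"] * 4)
        np.testing.assert_allclose(size_factors(cm).to_numpy(), 1.0)

    def test_doubled_column_splits_geometrically(self):
        """B = 2*A elementwise -> factors (1/sqrt(2), sqrt(2))."""
        arr = np.array([[10, 20], [30, 60], [7, 14]])
        cm = make_cm(arr, ["TL", "PROM"])
        np.testing.assert_allclose(
            size_factors(cm).to_numpy(), [2**-0.5, 2**0.5], rtol=1e-12
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        arr = rng.integers(1, 500, size=(30, 5))
        cm = make_cm(arr, ["TL"] * 5)
        perm = make_cm(arr[rng.permutation(30)], ["TL"] * 5)
        np.testing.assert_allclose(
            size_factors(cm).to_numpy(), size_factors(perm).to_numpy(), rtol=1e-12
        )

    def test_no_all_nonzero_gene_is_an_error(self):
        cm = make_cm(np.array([[0, 5], [5, 0]]), ["TL", "PROM"])
        with pytest.raises(ValueError, match="pre-filter"):
            size_factors(cm)


class TestNbTest:
    def test_identical_groups_are_null(self):
        res = nb_test([10] * 6, [10] * 6, UNIT, UNIT)
        assert res.log2fc == 0.0
        assert res.p_value > 0.99

    def test_doubled_means_force_log2fc_one(self):
        res = nb_test([10] * 6, [20] * 6, UNIT, UNIT)
        assert res.log2fc == pytest.approx(1.0)

    def test_all_zero_gene_flagged(self):
        res = nb_test([0] * 6, [0] * 6, UNIT, UNIT)
        assert res.flagged and res.p_value == 1.0 and res.log2fc == 0.0

    def test_label_swap_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ca = rng.negative_binomial(10, 0.1, 6)
            cb = rng.negative_binomial(10, 0.05, 6)
            fwd = nb_test(ca, cb, UNIT, UNIT)
            rev = nb_test(cb, ca, UNIT, UNIT)
            assert fwd.log2fc == pytest.approx(-rev.log2fc, abs=1e-12)
            # p symmetric up to the dispersion optimizer's convergence tolerance
            assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-4)

    def test_size_factors_absorb_sample_scaling(self):
        """Scaling one sample's counts, with factors absorbing it, keeps q within 10%."""
        rng = np.random.default_rng(10)
        arr = rng.negative_binomial(20, 20 / 120, size=(60, 12))
        cm = make_cm(arr, ["TL"] * 6 + ["PROM"] * 6)
        scaled_arr = arr.copy()
        scaled_arr[:, 0] *= 3
        scaled = make_cm(scaled_arr, ["TL"] * 6 + ["PROM"] * 6)
        f1, f2 = size_factors(cm), size_factors(scaled)
        gene = 7
        r1 = nb_test(arr[gene, :6], arr[gene, 6:], f1[:6].to_numpy(), f1[6:].to_numpy())
        r2 = nb_test(scaled_arr[gene, :6], scaled_arr[gene, 6:],
                     f2[:6].to_numpy(), f2[6:].to_numpy())
        assert r2.mean_a == pytest.approx(r1.mean_a, rel=0.1)
        assert r2.mean_b == pytest.approx(r1.mean_b, rel=0.1)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            nb_test([10], [10, 12], [1.0], [1.0, 1.0])

    def test_null_type_i_error_calibrated(self):
        """Null NB(mu=100, alpha=0.1), 6v6: p<0.01 fraction in [0.002, 0.02]."""
        rng = np.random.default_rng(7)
        r = 10  # 1/alpha
        p_nb = r / (r + 100)
        hits = 0
        n_genes = 2000
        for _ in range(n_genes):
            res = nb_test(rng.negative_binomial(r, p_nb, 6),
                          rng.negative_binomial(r, p_nb, 6), UNIT, UNIT)
            hits += res.p_value < 0.01
        assert 0.002 <= hits / n_genes <= 0.02

    def test_log2fc_recovery_within_tolerance(self):
        """Median estimated log2fc within +-0.3 of the planted value at mu>=100."""
        rng = np.random.default_rng(3)
        r = 20  # alpha = 0.05
        errs = []
        for _ in range(100):
            ca = rng.negative_binomial(r, r / (r + 150), 6)
            cb = rng.negative_binomial(r, r / (r + 600), 6)
            errs.append(nb_test(ca, cb, UNIT, UNIT).log2fc - 2.0)
        assert abs(np.median(errs)) <= 0.3


class TestCallDegs:
    def make_results(self, rows):
        return pd.DataFrame(
            [(f"g{i}", 1.0, 1.0, lfc, p, "none") for i, (lfc, p) in enumerate(rows)],
            columns=["gene_id", "mean_a", "mean_b", "log2fc", "p_value", "direction"],
        )

    @pytest.mark.parametrize(
        "log2fc, p, expected",
        [
            (np.log2(2.5), 0.005, "up"),     # passes both study thresholds
            (np.log2(1.8), 0.005, "none"),   # fails the fold-change rule
            (2.0, 0.02, "none"),             # fails the p rule
            (1.0, 0.005, "up"),              # FC exactly 2: inclusive boundary
            (-1.0, 0.005, "down"),
        ],
    )
    def test_threshold_rules(self, log2fc, p, expected):
        out = call_degs(self.make_results([(log2fc, p)]))
        assert out["direction"].iloc[0] == expected

    def test_strict_mode_excludes_boundary(self):
        out = call_degs(self.make_results([(1.0, 0.005)]), strict_fc=True)
        assert out["direction"].iloc[0] == "none"

    def test_invalid_thresholds_rejected(self):
        results = self.make_results([(1.0, 0.5)])
        with pytest.raises(ValueError):
            call_degs(results, p_threshold=1.5)
        with pytest.raises(ValueError):
            call_degs(results, fc_threshold=0.9)


class TestContrastTables:
    def test_parse_contrast(self):
        assert parse_contrast("PTB_vs_TL") == ("PTB", "TL")
        with pytest.raises(ValueError):
            parse_contrast("PTBvsTL")

    def test_count_table_conserves_and_zero_case(self):
        empty = pd.DataFrame(
            columns=["gene_id", "mean_a", "mean_b", "log2fc", "p_value", "direction"]
        )
        table = deg_count_table({"PTB_vs_TL": empty})
        assert table.iloc[0][["up", "down", "total"]].tolist() == [0, 0, 0]

    def test_planted_effects_recovered_in_contrast(self):
        """150 up + 150 down planted at log2fc +-2 (mu=200): >=120 called each way."""
        rng = np.random.default_rng(3)
        r = 20  # alpha = 0.05
        n_each = 150
        mu = 200
        rows = []
        for i in range(2 * n_each + 200):
            mu_b = mu * 4 if i < n_each else (mu / 4 if i < 2 * n_each else mu)
            rows.append(np.concatenate([
                rng.negative_binomial(r, r / (r + mu), 6),
                rng.negative_binomial(r, r / (r + mu_b), 6),
            ]))
        cm = make_cm(np.array(rows), ["TL"] * 6 + ["PTB"] * 6)
        called = call_degs(de_contrast(cm, "PTB_vs_TL"))
        sets = deg_sets(called)
        planted_up = {f"g{i}" for i in range(n_each)}
        planted_down = {f"g{i}" for i in range(n_each, 2 * n_each)}
        assert len(sets["up"] & planted_up) >= 120
        assert len(sets["down"] & planted_down) >= 120
        table = deg_count_table({"PTB_vs_TL": called})
        assert (table["total"] == table["up"] + table["down"]).all()
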