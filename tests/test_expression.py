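"""Normalization, moderated statistics, calling, clustering, percentages."""

import numpy as np
import pandas as pd
import pytest

from ahrcross.expression import (
    call_de,
    cluster_de_profiles,
    collapse_any_time,
    fit_empirical_bayes,
    normalize,
    posterior_activity,
    response_percentage,
    signed_fold_change,
)
from ahrcross.io import ExpressionTable, FormatError
from ahrcross.simulate import generate_experiment


def _ratio_table(m: np.ndarray, probes=None, genes=None) -> ExpressionTable:
    """Wrap a probe x array matrix of log2 ratios as an ExpressionTable."""
    n = m.shape[0]
    probes = probes or [f"p{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(n)]
    values = pd.DataFrame(m, index=probes, columns=[f"arr{j}" for j in range(m.shape[1])])
    return ExpressionTable(values, pd.Series(genes, index=probes), "log2_ratio")


def _ratio_sheet(n_arrays: int, species="mouse", time_hr=4.0) -> pd.DataFrame:
    rows = []
    for j in range(n_arrays):
        for trt, dye in (("TCDD", "Cy5"), ("vehicle", "Cy3")):
            rows.append(
                dict(
                    sample_id=f"arr{j}_{trt}",
                    species=species,
                    treatment=trt,
                    time_hr=time_hr,
                    dye=dye,
                    replicate=j + 1,
                    array_id=f"arr{j}",
                )
            )
    return pd.DataFrame(rows)


class TestNormalize:
    def test_planted_dye_bias_removed_from_nulls(self):
        table, sheet, _, truth = generate_experiment(
            n_genes=500, proportions={"null": 1.0}, times=(4.0,),
            species=("mouse",), seed=2,
        )
        norm = normalize(table, sheet)
        mean_m = norm.values.mean(axis=1)
        assert abs(mean_m.mean()) < 0.05

    def test_bias_free_input_near_identity(self):
        table, sheet, _, _ = generate_experiment(
            n_genes=300, proportions={"null": 1.0}, times=(4.0,),
            species=("mouse",), dye_bias=lambda a: np.zeros_like(a), seed=3,
        )
        norm = normalize(table, sheet)
        # recompute raw oriented M for one array and compare
        arr = sheet["array_id"].iloc[0]
        pair = sheet[sheet["array_id"] == arr]
        treated = pair[pair["treatment"] == "TCDD"]["sample_id"].iloc[0]
        control = pair[pair["treatment"] == "vehicle"]["sample_id"].iloc[0]
        raw_m = np.log2(table.values[treated]) - np.log2(table.values[control])
        diff = (norm.values[arr] - raw_m).abs()
        assert diff.max() < 0.05

    def test_constant_shift_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(7, 13, 200)
        m = np.full(200, 0.5)
        cy5 = 2.0 ** (a + m / 2)
        cy3 = 2.0 ** (a - m / 2)
        values = pd.DataFrame(
            {"arr0_TCDD": cy5, "arr0_vehicle": cy3},
            index=[f"p{i}" for i in range(200)],
        )
        table = ExpressionTable(
            values, pd.Series([f"g{i}" for i in range(200)], index=values.index),
            "raw_two_channel",
        )
        norm = normalize(table, _ratio_sheet(1))
        assert norm.values["arr0"].abs().mean() < 0.05

    def test_equal_intensity_probes_keep_rank_order(self):
        # probes at identical A get the same trend offset, so M order persists
        rng = np.random.default_rng(1)
        a = np.concatenate([np.full(50, 10.0), rng.uniform(7, 13, 150)])
        m = rng.normal(0, 1, 200)
        cy5 = 2.0 ** (a + m / 2)
        cy3 = 2.0 ** (a - m / 2)
        values = pd.DataFrame(
            {"arr0_TCDD": cy5, "arr0_vehicle": cy3},
            index=[f"p{i}" for i in range(200)],
        )
        table = ExpressionTable(
            values, pd.Series([f"g{i}" for i in range(200)], index=values.index),
            "raw_two_channel",
        )
        norm = normalize(table, _ratio_sheet(1))
        block = norm.values["arr0"].iloc[:50].to_numpy()
        assert (np.argsort(block) == np.argsort(m[:50])).all()

    def test_too_few_probes_rejected(self):
        values = pd.DataFrame(
            {"arr0_TCDD": [2.0] * 5, "arr0_vehicle": [1.0] * 5},
            index=[f"p{i}" for i in range(5)],
        )
        table = ExpressionTable(
            values, pd.Series([f"g{i}" for i in range(5)], index=values.index),
            "raw_two_channel",
        )
        with pytest.raises(FormatError, match="pass"):
            normalize(table, _ratio_sheet(1))


class TestEmpiricalBayes:
    def test_strong_effect_tiny_variance_has_high_p1(self):
        m = np.vstack(
            [
                np.array([3.0, 3.001, 2.999]),
                *[np.random.default_rng(i).normal(0, 0.2, 3) for i in range(60)],
            ]
        )
        stats = fit_empirical_bayes(_ratio_table(m), _ratio_sheet(3))
        assert stats.iloc[0]["p1"] > 0.999

    def test_null_data_rarely_called(self):
        rng = np.random.default_rng(10)
        m = rng.normal(0, 0.2, size=(2000, 6))
        stats = fit_empirical_bayes(_ratio_table(m), _ratio_sheet(6))
        frac = (stats["p1"] > 0.999).mean()
        assert frac <= 0.005

    def test_p1_monotone_in_abs_t(self):
        t = np.array([-5.0, -2.0, -0.1, 0.0, 0.1, 2.0, 5.0, 20.0])
        p1 = posterior_activity(t, np.full_like(t, 10.0))
        order = np.argsort(np.abs(t), kind="stable")
        assert (np.diff(p1[order]) >= -1e-12).all()
        assert p1[np.abs(t).argmax()] == p1.max()

    def test_replicate_permutation_leaves_stats_unchanged(self):
        rng = np.random.default_rng(4)
        m = rng.normal(0.5, 0.3, size=(100, 4))
        base = fit_empirical_bayes(_ratio_table(m), _ratio_sheet(4))
        perm = fit_empirical_bayes(
            _ratio_table(m[:, [2, 0, 3, 1]]), _ratio_sheet(4)
        )
        np.testing.assert_allclose(base["t_mod"], perm["t_mod"], atol=1e-12)
        np.testing.assert_allclose(base["p1"], perm["p1"], atol=1e-12)

    def test_too_few_replicates_rejected(self):
        m = np.zeros((30, 1))
        with pytest.raises(FormatError, match="replicates"):
            fit_empirical_bayes(_ratio_table(m), _ratio_sheet(1))

    def test_fold_change_magnitude_at_least_one(self):
        m_bar = np.array([-3.0, -0.1, 0.0, 0.1, 3.0])
        fc = signed_fold_change(m_bar)
        assert (np.abs(fc) >= 1.0).all()
        assert fc[0] == -8.0 and fc[-1] == 8.0 and fc[2] == 1.0


class TestCallDe:
    @pytest.mark.parametrize(
        "p1,fc,expect_sig,expect_dir",
        [
            (0.9995, 1.5, True, "up"),
            (0.9995, -1.5, True, "down"),
            (0.9995, 1.4, False, "ns"),  # |fc| threshold is strict
            (0.999, 5.0, False, "ns"),  # p1 threshold is strict
            (0.99951, 1.41, True, "up"),
        ],
    )
    def test_strict_boundaries(self, p1, fc, expect_sig, expect_dir):
        df = pd.DataFrame(
            {"gene_id": ["g"], "p1": [p1], "fc": [fc]}
        )
        out = call_de(df)
        assert bool(out["significant"].iloc[0]) is expect_sig
        assert out["direction"].iloc[0] == expect_dir

    def test_any_time_is_or_over_conditions(self):
        df = pd.DataFrame(
            {
                "species": ["m"] * 4,
                "gene_id": ["g1", "g1", "g2", "g2"],
                "probe_id": ["g1p", "g1p", "g2p", "g2p"],
                "time_hr": [4.0, 12.0] * 2,
                "p1": [0.5, 0.9999, 0.5, 0.6],
                "fc": [1.1, 2.0, 1.1, 1.2],
            }
        )
        out = collapse_any_time(call_de(df))
        byg = out.set_index("gene_id")
        assert bool(byg.loc["g1", "any_time"]) is True
        assert byg.loc["g1", "direction"] == "up"
        assert bool(byg.loc["g2", "any_time"]) is False


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        link, labels, _ = cluster_de_profiles(mat)
        assert link[0, 2] == pytest.approx(0.0)

    def test_hand_computed_first_merge(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [0.0, 3.0], [4.0, 0.0]], index=["a", "b", "c"]
        )
        link, labels, _ = cluster_de_profiles(mat)
        assert link[0, 2] == pytest.approx(3.0)  # a-b pair at distance 3
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            rng.normal(size=(8, 5)), index=[f"g{i}" for i in range(8)]
        )
        link1, labels1, order1 = cluster_de_profiles(mat)
        link2, labels2, order2 = cluster_de_profiles(mat.sample(frac=1, random_state=0))
        np.testing.assert_allclose(link1, link2)
        assert labels1 == labels2 and order1 == order2

    def test_missing_values_use_scaled_pairwise_complete(self):
        mat = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0], [3.0, np.nan, 3.0, np.nan]], index=["a", "b"]
        )
        link, _, _ = cluster_de_profiles(mat)
        # observed squared distance 18 over 2 of 4 dims -> scaled to 36
        assert link[0, 2] == pytest.approx(6.0)

    def test_all_missing_row_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]], index=["a", "b"])
        with pytest.raises(FormatError, match="no observed"):
            cluster_de_profiles(mat)


class TestResponsePercentage:
    @pytest.mark.parametrize(
        "n_de,n_total,expected",
        [
            (691, 6995, 9.9),
            (439, 8478, 5.2),
            (57, 5169, 1.1),
            (8, 3850, 0.2),
            (0, 5000, 0.0),
        ],
    )
    def test_reported_percentages(self, n_de, n_total, expected):
        assert response_percentage(n_de, n_total) == expected

    def test_round_half_up(self):
        assert response_percentage(25, 1000) == 2.5
        assert response_percentage(125, 10000) == 1.3  # 1.25 rounds up

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            response_percentage(0, 0)
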