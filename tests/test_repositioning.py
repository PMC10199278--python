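"""Correlation engine: Spearman, optimal conditions, ranking, consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, spearmanr

from kdmimic import (
    ConstantVectorError,
    SignatureMatrix,
    build_consensus,
    correlate_profiles,
    rank_and_flag_top,
    reposition,
    select_optimal_condition,
    spearman_rho,
)
from kdmimic.repositioning import META_COLUMNS


class TestSpearman:
    def test_identity(self, rng):
        x = rng.normal(size=10)
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_closed_form_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-2, 1, 1)
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_antimonotone(self, rng):
        x = rng.normal(size=20)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=(2, 20))
            assert spearman_rho(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12
            )

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 15))
        assert spearman_rho(x, y) == spearman_rho(y, x)

    def test_constant_vector_signalled(self):
        with pytest.raises(ConstantVectorError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=30, unique=True))
    def test_monotone_transform_invariance(self, xs):
        x = np.array(xs)
        y = np.sin(x) + x  # arbitrary paired values
        # mapping distinct values to their ranks is strictly monotone and
        # exact in floating point, unlike exp/power transforms
        assert spearman_rho(rankdata(x) * 3 + 1, y) == pytest.approx(
            spearman_rho(x, y), abs=1e-12
        )


def _toy_matrices(rng, n_genes=20, n_kd=3, n_drug_sigs=8):
    genes = [f"G{i}" for i in range(n_genes)]
    kd_ids = [f"L:KD:GLS:{i}" for i in range(1, n_kd + 1)]
    drug_ids, meta_rows = [], []
    for sig in kd_ids:
        meta_rows.append((sig, "knockdown", "GLS", "L", np.nan, np.nan))
    for i in range(n_drug_sigs):
        drug, dose, time = f"d{i // 4}", [1.0, 10.0][i % 2], [6.0, 24.0][(i // 2) % 2]
        sig = f"L:{drug}:{dose}:{time}:{i}"
        drug_ids.append(sig)
        meta_rows.append((sig, "compound", drug, "L", dose, time))
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    kd = SignatureMatrix(genes, kd_ids, rng.normal(size=(n_genes, n_kd)))
    drugs = SignatureMatrix(genes, drug_ids, rng.normal(size=(n_genes, n_drug_sigs)))
    return kd, drugs, meta


class TestCorrelateProfiles:
    def test_cardinality_forced(self, rng):
        kd, drugs, meta = _toy_matrices(rng)
        assert len(correlate_profiles(kd, drugs, meta)) == 3 * 8

    def test_identical_signature_has_rho_one(self, rng):
        kd, drugs, meta = _toy_matrices(rng)
        drugs.values[:, 0] = kd.values[:, 0]
        corr = correlate_profiles(kd, drugs, meta)
        row = corr[(corr["drug_sig_id"] == drugs.sig_ids[0])
                   & (corr["kd_sig_id"] == kd.sig_ids[0])]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        kd, drugs, meta = _toy_matrices(rng)
        corr = correlate_profiles(kd, drugs, meta)
        for row in corr.itertuples():
            a = rankdata(kd.column(row.kd_sig_id))
            b = rankdata(drugs.column(row.drug_sig_id))
            assert row.rho == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_gene_universe_mismatch_rejected(self, rng):
        kd, drugs, meta = _toy_matrices(rng)
        drugs.gene_ids = [g + "x" for g in drugs.gene_ids]
        with pytest.raises(ValueError):
            correlate_profiles(kd, drugs, meta)


class TestOptimalCondition:
    def _corr(self, rows):
        return pd.DataFrame(
            rows,
            columns=["cell_line", "drug", "dose_um", "time_h",
                     "drug_sig_id", "kd_sig_id", "rho"],
        )

    def test_max_selected(self):
        corr = self._corr(
            [("L", "d", 1.0, 6.0, "s1", "k", 0.2), ("L", "d", 10.0, 24.0, "s2", "k", 0.7)]
        )
        best = select_optimal_condition(corr)
        assert best["best_rho"].iloc[0] == 0.7
        assert best["best_dose"].iloc[0] == 10.0
        assert best["best_time"].iloc[0] == 24.0

    def test_tie_breaks_to_low_dose_early_time(self):
        corr = self._corr(
            [("L", "d", 10.0, 24.0, "s1", "k", 0.5), ("L", "d", 1.0, 6.0, "s2", "k", 0.5)]
        )
        best = select_optimal_condition(corr)
        assert best["best_dose"].iloc[0] == 1.0
        assert best["best_time"].iloc[0] == 6.0

    def test_matches_exhaustive_max_over_replicates(self, rng):
        kd, drugs, meta = _toy_matrices(rng, n_kd=3)
        corr = correlate_profiles(kd, drugs, meta)
        best = select_optimal_condition(corr).set_index("drug")
        for drug, grp in corr.groupby("drug"):
            assert best.loc[drug, "best_rho"] == pytest.approx(grp["rho"].max())

    def test_mean_reduction_option(self):
        corr = self._corr(
            [("L", "d", 1.0, 6.0, "s1", "k1", 0.0), ("L", "d", 1.0, 6.0, "s1", "k2", 1.0)]
        )
        assert select_optimal_condition(corr, kd_reduce="mean")["best_rho"].iloc[0] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_condition(self._corr([]))


class TestRankAndFlag:
    def _best(self, rhos):
        return pd.DataFrame(
            {
                "cell_line": "L",
                "drug": [f"d{i:04d}" for i in range(len(rhos))],
                "best_rho": rhos,
                "best_dose": 1.0,
                "best_time": 6.0,
            }
        )

    @pytest.mark.parametrize("n,expected", [(700, 7), (50, 1), (100, 1), (101, 2)])
    def test_ceil_count(self, n, expected, rng):
        tbl = rank_and_flag_top(self._best(rng.normal(size=n)))
        assert int(tbl["top1"].sum()) == expected

    def test_highest_rho_is_rank_one(self, rng):
        tbl = rank_and_flag_top(self._best(rng.normal(size=30)))
        top = tbl[tbl["rank"] == 1]
        assert top["best_rho"].iloc[0] == tbl["best_rho"].max()
        assert bool(top["top1"].iloc[0])

    def test_ranks_are_permutation(self, rng):
        tbl = rank_and_flag_top(self._best(rng.normal(size=57)))
        assert sorted(tbl["rank"]) == list(range(1, 58))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_and_flag_top(self._best([0.1, math.nan]))


class TestConsensus:
    def _rank_table(self, ranks_flags):
        return pd.DataFrame(
            {
                "drug": list(ranks_flags),
                "rank": [r for r, _ in ranks_flags.values()],
                "top1": [f for _, f in ranks_flags.values()],
            }
        )

    def test_threshold_application(self):
        lines = {}
        for i in range(7):
            flags = {
                "all7": (1, True),
                "six": (2, i < 6),
                "five": (3, i < 5),
                "never": (50, False),
            }
            lines[f"L{i}"] = self._rank_table(flags)
        cons = build_consensus(lines, set1_min_lines=6, set2_min_lines=2, n_top=4)
        label = cons.set_index("drug")["set_label"]
        assert label["all7"] == "SET1"
        assert label["six"] == "SET1"
        assert label["five"] == "SET2"
        assert label["never"] == "none"

    def test_set2_median_rank_hand_example(self):
        # B,C,D top-1% in two of three lines with ranks {2,4},{1,9},{3,3}:
        # medians 3, 5, 3; n_top=2 keeps B and D (tie broken by mean then label)
        l1 = self._rank_table({"B": (2, True), "C": (1, True), "D": (3, True)})
        l2 = self._rank_table({"B": (4, True), "C": (9, True), "D": (3, True)})
        l3 = self._rank_table({"Z": (1, True)})  # B,C,D not assayed here
        cons = build_consensus(
            {"L1": l1, "L2": l2, "L3": l3},
            set1_min_lines=3, set2_min_lines=2, n_top=2,
        )
        assert list(cons.loc[cons["set_label"] == "SET2", "drug"]) == ["B", "D"]
        assert set(cons.loc[cons["set_label"] == "SET1", "drug"]) == set()
        label = cons.set_index("drug")["set_label"]
        assert label["C"] == "none" and label["Z"] == "none"

    def test_sets_disjoint(self, small_compendium):
        cfg, mats, meta = small_compendium
        res = reposition(mats, meta, "GLS", set1_min_lines=3, set2_min_lines=2)
        cons = res["consensus"]
        s1 = set(cons.loc[cons["set_label"] == "SET1", "drug"])
        s2 = set(cons.loc[cons["set_label"] == "SET2", "drug"])
        assert not s1 & s2

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            build_consensus({"L1": self._rank_table({"A": (1, True)})},
                            set1_min_lines=6)


class TestEndToEnd:
    def test_mimic_recovered_and_deterministic(self, small_compendium):
        cfg, mats, meta = small_compendium
        res = reposition(mats, meta, "GLS", set1_min_lines=3, set2_min_lines=2)
        cons = res["consensus"].set_index("drug")
        assert cons.loc["mimic", "set_label"] == "SET1"
        assert cons.loc["mimic", "n_lines_top1"] == 3
        res2 = reposition(mats, meta, "GLS", set1_min_lines=3, set2_min_lines=2)
        pd.testing.assert_frame_equal(res["consensus"], res2["consensus"])

    def test_rank_invariance_under_monotone_transform(self, small_compendium):
        cfg, mats, meta = small_compendium
        line = cfg.cell_lines[0]
        warped = {
            line: SignatureMatrix(
                mats[line].gene_ids,
                mats[line].sig_ids,
                np.tanh(mats[line].values) + mats[line].values / 10,
            )
        }
        orig = {line: mats[line]}
        kw = dict(set1_min_lines=1, set2_min_lines=1)
        r1 = reposition(orig, meta, "GLS", **kw)["ranks"][line]
        r2 = reposition(warped, meta, "GLS", **kw)["ranks"][line]
        pd.testing.assert_series_equal(r1["drug"], r2["drug"])
        pd.testing.assert_series_equal(r1["rank"], r2["rank"])
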