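import itertools

import numpy as np
import pandas as pd
import pytest

from nmdtools.expression import (
    CountMatrix,
    DeTable,
    DependenceConfig,
    NmdCallConfig,
    bh_adjust,
    call_dependence_groups,
    call_nmd_targets,
    compute_tpm,
    filter_expressed,
    nmd_efficiency_per_gene,
    select_stringent_set,
    simple_de,
    size_factors,
)
from nmdtools.ptc import PtcGrouping


def _matrix(values, samples, conditions, lengths=None, ids=None):
    ids = ids or [f"r{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=ids, columns=samples)
    lens = pd.Series(lengths, index=ids) if lengths is not None else None
    return CountMatrix(counts=df, conditions=conditions, lengths=lens)


def _de_table(rows, contrast=("test", "ref")):
    """rows: {id: (log2fc, padj)}"""
    df = pd.DataFrame(
        {
            "log2_fold_change": {k: v[0] for k, v in rows.items()},
            "p_value": {k: v[1] for k, v in rows.items()},
            "adjusted_p": {k: v[1] for k, v in rows.items()},
        }
    )
    return DeTable(table=df, contrast=contrast)


class TestTpmAndFilter:
    def test_equal_lengths_split_evenly(self):
        cm = _matrix([[10], [10]], ["s1"], {"s1": "a"}, lengths=[1000, 1000])
        tpm = compute_tpm(cm)
        assert np.allclose(tpm["s1"], [500_000, 500_000])

    def test_length_normalization(self):
        cm = _matrix([[10], [10]], ["s1"], {"s1": "a"}, lengths=[1000, 2000])
        tpm = compute_tpm(cm)
        assert np.allclose(tpm["s1"], [1e6 * 2 / 3, 1e6 / 3])

    def test_single_row_is_1e6(self):
        cm = _matrix([[7]], ["s1"], {"s1": "a"}, lengths=[500])
        assert compute_tpm(cm)["s1"].iloc[0] == pytest.approx(1e6)

    def test_columns_sum_to_1e6(self, rng):
        counts = rng.poisson(50, size=(40, 6)).astype(float)
        samples = [f"s{i}" for i in range(6)]
        cm = _matrix(counts, samples, {s: "a" for s in samples},
                     lengths=rng.integers(200, 3000, size=40))
        assert np.allclose(compute_tpm(cm).sum(axis=0), 1e6)

    def test_filter_low_in_all_conditions_removed(self):
        tpm = pd.DataFrame(
            {"a_r1": [0.5, 0.5, 0.0], "b_r1": [0.5, 1.3, 2.0], "c_r1": [0.5, 0.2, 0.0]},
            index=["low", "mid", "hi"],
        )
        conds = {"a_r1": "a", "b_r1": "b", "c_r1": "c"}
        assert filter_expressed(tpm, conds) == {"mid", "hi"}
        assert filter_expressed(tpm, conds, threshold=0.0) == {"low", "mid", "hi"}

    def test_filter_uses_condition_means(self):
        # per-replicate TPM crosses 1 but the condition mean does not
        tpm = pd.DataFrame({"a_r1": [1.8], "a_r2": [0.1]}, index=["x"])
        conds = {"a_r1": "a", "a_r2": "a"}
        assert filter_expressed(tpm, conds) == set()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(100, size=30).astype(float) + 1
        df = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        assert np.allclose(size_factors(df), 1.0)

    def test_scale_equivariance(self, rng):
        col = rng.poisson(100, size=30).astype(float) + 1
        df = pd.DataFrame({"s1": col, "s2": 2 * col})
        sf = size_factors(df)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(50, 4)).astype(float)
        df = pd.DataFrame(counts, columns=list("abcd"))
        sf = size_factors(df)
        # independent row-by-row oracle
        import math

        geomeans = [
            math.exp(sum(math.log(c) for c in row) / len(row)) if all(c > 0 for c in row) else 0.0
            for row in counts
        ]
        for j, col in enumerate("abcd"):
            ratios = sorted(
                counts[i, j] / geomeans[i]
                for i in range(50)
                if geomeans[i] > 0
            )
            expected = float(np.median(ratios))
            assert sf[col] == pytest.approx(expected, rel=1e-12)

    def test_no_all_positive_row_errors(self):
        df = pd.DataFrame({"s1": [0.0, 5.0], "s2": [3.0, 0.0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(df)


class TestSimpleDe:
    def test_equal_means_zero_lfc(self, rng):
        vals = rng.poisson(80, size=(20, 2))
        df = np.concatenate([vals, vals], axis=1).astype(float)
        cm = _matrix(df, ["t1", "t2", "r1", "r2"],
                     {"t1": "t", "t2": "t", "r1": "r", "r2": "r"})
        de = simple_de(cm, ("t", "r"))
        assert np.allclose(de.table["log2_fold_change"], 0.0)

    def test_pseudocounted_fold_change(self):
        # normalized means 30 vs 10 -> log2(30.5/10.5); the null rows are
        # column-identical so the size factors are exactly 1
        null_rows = [[v] * 4 for v in (60, 80, 100, 120, 140, 160, 180, 200, 220)]
        cm = _matrix(
            [[30, 30, 10, 10]] + null_rows,
            ["t1", "t2", "r1", "r2"],
            {"t1": "t", "t2": "t", "r1": "r", "r2": "r"},
        )
        de = simple_de(cm, ("t", "r"))
        assert de.table.loc["r0", "log2_fold_change"] == pytest.approx(
            np.log2(30.5 / 10.5), abs=1e-9
        )

    def test_antisymmetric_under_contrast_swap(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(60, 6)).astype(float) + 50
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        cm = _matrix(counts, samples,
                     {s: s[0] for s in samples})
        fwd = simple_de(cm, ("a", "b")).table["log2_fold_change"]
        rev = simple_de(cm, ("b", "a")).table["log2_fold_change"]
        assert np.abs(fwd + rev).max() < 0.01

    def test_single_replicate_gives_fc_only(self):
        cm = _matrix([[30, 10], [50, 50]], ["t1", "r1"], {"t1": "t", "r1": "r"})
        de = simple_de(cm, ("t", "r"))
        assert de.table["p_value"].isna().all()
        assert de.table["log2_fold_change"].notna().all()

    def test_sign_recovery_on_injected_effect(self, rng):
        """1.5x effect in 10% of rows, mean 100, n=3 vs 3: sign of log2FC
        correct for >= 95% of true-effect rows."""
        m, frac = 500, 0.1
        n_eff = int(m * frac)
        mu = np.full(m, 100.0)
        mu_t = mu.copy()
        mu_t[:n_eff] *= 1.5
        disp = 0.05
        n_param = 1 / disp
        t_cols = {f"t{i}": rng.negative_binomial(n_param, n_param / (n_param + mu_t))
                  for i in range(3)}
        r_cols = {f"r{i}": rng.negative_binomial(n_param, n_param / (n_param + mu))
                  for i in range(3)}
        df = pd.DataFrame({**t_cols, **r_cols}).astype(float)
        conds = {c: ("t" if c.startswith("t") else "r") for c in df.columns}
        cm = CountMatrix(counts=df, conditions=conds)
        de = simple_de(cm, ("t", "r"))
        correct = (de.table["log2_fold_change"].iloc[:n_eff] > 0).mean()
        assert correct >= 0.95

    def test_missing_condition_errors(self):
        cm = _matrix([[1, 2]], ["s1", "s2"], {"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="absent"):
            simple_de(cm, ("a", "zzz"))


class TestBhAdjust:
    def test_hand_computed_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_equal_values(self):
        assert bh_adjust([0.04]).iloc[0] == pytest.approx(0.04)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_nan_propagates_and_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out.iloc[1])
        assert out.iloc[0] == pytest.approx(0.02)  # m = 2

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p).to_numpy()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallNmdTargets:
    def _tables(self, per_condition):
        """per_condition: list of {id: (fc_linear, padj)}"""
        return [
            _de_table({k: (np.log2(fc), p) for k, (fc, p) in cond.items()})
            for cond in per_condition
        ]

    def test_two_of_three_up_is_nmd_plus(self):
        tables = self._tables([
            {"x": (1.3, 0.01)}, {"x": (1.25, 0.04)}, {"x": (1.0, 0.9)},
        ])
        plus, minus = call_nmd_targets(tables)
        assert plus == {"x"} and minus == set()

    def test_flat_in_two_is_nmd_minus(self):
        tables = self._tables([
            {"x": (1.1, 0.5)}, {"x": (0.95, 0.5)}, {"x": (1.05, 0.5)},
        ])
        plus, minus = call_nmd_targets(tables)
        assert minus == {"x"} and plus == set()

    def test_one_supporting_condition_is_neither(self):
        tables = self._tables([
            {"x": (1.3, 0.01)}, {"x": (1.3, 0.20)}, {"x": (1.0, 0.9)},
        ])
        plus, minus = call_nmd_targets(tables)
        # one significant-up condition; flat only in condition 3
        assert "x" not in plus and "x" not in minus

    def test_matches_exhaustive_truth_table(self):
        """Every combination of per-condition states (sig-up / flat / other)
        across 3 conditions agrees with a brute-force rule evaluation."""
        # state -> (linear fc, padj)
        states = {
            "up": (1.5, 0.001),     # significant and > 1.2
            "flat": (1.05, 0.5),    # |fc| < 1.2
            "other": (1.3, 0.8),    # up but not significant; not flat
            "down": (0.5, 0.001),   # significant down; not flat
        }
        combos = list(itertools.product(states, repeat=3))
        rows = {f"c{i}": combo for i, combo in enumerate(combos)}
        tables = self._tables([
            {rid: states[combo[k]] for rid, combo in rows.items()}
            for k in range(3)
        ])
        plus, minus = call_nmd_targets(tables)
        for rid, combo in rows.items():
            n_up = sum(s == "up" for s in combo)
            n_flat = sum(s == "flat" for s in combo)
            expect_plus = n_up >= 2
            expect_minus = n_flat >= 2 and not expect_plus
            assert (rid in plus) == expect_plus, (rid, combo)
            assert (rid in minus) == expect_minus, (rid, combo)

    def test_requires_three_tables(self):
        with pytest.raises(ValueError, match="3 condition"):
            call_nmd_targets(self._tables([{"x": (1.0, 0.5)}] * 2))


class TestDependenceGroups:
    def test_thresholds(self):
        table = _de_table({
            "dep": (np.log2(1.6), 0.001),
            "ind": (np.log2(1.05), 0.3),
            "gap": (np.log2(1.35), 0.001),
            "dep_nonsig": (np.log2(1.6), 0.3),
        })
        dep, ind = call_dependence_groups(table)
        assert dep == {"dep"}
        assert ind == {"ind"}
        assert "gap" not in dep | ind

    def test_up_fc_boundary_configurable(self):
        table = _de_table({"x": (np.log2(1.5), 0.001)})
        dep_incl, _ = call_dependence_groups(
            table, DependenceConfig(up_inclusive=True)
        )
        dep_strict, _ = call_dependence_groups(
            table, DependenceConfig(up_inclusive=False)
        )
        assert dep_incl == {"x"} and dep_strict == set()


class TestStringentSet:
    def test_filters_by_gene_list(self):
        gene_of = {f"t{i}": f"g{i}" for i in range(5)}
        got = select_stringent_set(
            set(gene_of), {"g1", "g3"}, gene_of
        )
        assert got == {"t1", "t3"}

    def test_one_isoform_per_gene_by_tpm(self):
        gene_of = {"tA": "g", "tB": "g"}
        tpm = pd.Series({"tA": 5.0, "tB": 9.0})
        got = select_stringent_set({"tA", "tB"}, {"g"}, gene_of, mean_tpm=tpm)
        assert got == {"tB"}
        # tie -> lexicographic
        tpm_tie = pd.Series({"tA": 5.0, "tB": 5.0})
        got = select_stringent_set({"tA", "tB"}, {"g"}, gene_of, mean_tpm=tpm_tie)
        assert got == {"tA"}

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning):
            assert select_stringent_set({"t"}, set(), {"t": "g"}) == set()


class TestNmdEfficiency:
    def _grouping(self):
        return PtcGrouping(
            ptc_plus={"g1.p1", "g1.p2", "g2.p", "g3.p"},
            ptc_minus={"g1.m", "g2.m", "g3.m"},
            gene_index={
                "g1": ({"g1.p1", "g1.p2"}, {"g1.m"}),
                "g2": ({"g2.p"}, {"g2.m"}),
                "g3": ({"g3.p"}, {"g3.m"}),
                "g4": ({"g4.p"}, set()),  # no PTC- isoform: excluded
            },
        )

    def test_max_over_isoforms_and_bins(self):
        table = _de_table({
            "g1.p1": (np.log2(1.2), 0.5),
            "g1.p2": (np.log2(1.9), 0.01),
            "g2.p": (0.0, 0.9),
            "g3.p": (np.log2(0.6), 0.01),
            "g4.p": (np.log2(2.0), 0.01),
        })
        eff = nmd_efficiency_per_gene(table, self._grouping())
        assert eff.loc["g1", "fold_change"] == pytest.approx(1.9)
        assert eff.loc["g1", "bin"] == "up"
        assert eff.loc["g2", "bin"] == "no_change"
        assert eff.loc["g3", "bin"] == "down"
        assert "g4" not in eff.index
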