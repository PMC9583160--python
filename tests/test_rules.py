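"""Discretization, transaction encoding, Apriori and rule statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ncycle as nc
from ncycle.rules import TransactionDB


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracles
# ---------------------------------------------------------------------------


def brute_force_frequent(db, min_support, max_len=None):
    alphabet = sorted(db.alphabet)
    out = {}
    for k in range(1, (max_len or len(alphabet)) + 1):
        for combo in itertools.combinations(alphabet, k):
            s = frozenset(combo)
            supp = sum(1 for t in db.transactions if s <= t) / db.n
            if supp >= min_support:
                out[s] = supp
    return out


def brute_force_rules(db, min_support, min_confidence):
    out = set()
    for itemset, supp in brute_force_frequent(db, min_support).items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for con in itertools.combinations(sorted(itemset), r):
                con = frozenset(con)
                ant = itemset - con
                conf = supp / db.support(ant)
                if conf >= min_confidence:
                    out.add((ant, con, round(supp, 12), round(conf, 12)))
    return out


def random_db(rng, max_items=8, max_tx=20):
    n_items = rng.integers(2, max_items + 1)
    alphabet = [f"v{i}=c" for i in range(n_items)]
    n_tx = rng.integers(1, max_tx + 1)
    txs = []
    for _ in range(n_tx):
        mask = rng.random(n_items) < rng.uniform(0.2, 0.8)
        txs.append(frozenset(a for a, m in zip(alphabet, mask) if m))
    return TransactionDB(txs, [f"s{i}" for i in range(n_tx)])


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_three_bins_at_30_70_percentiles(self):
        vals = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        disc = nc.discretize(vals, scheme=3)
        lo, hi = np.percentile(vals, [30, 70])
        assert disc.cut_points == (pytest.approx(lo), pytest.approx(hi))
        for v, cat in zip(vals, disc.categories):
            if v <= lo:
                assert cat == "<30%"
            elif v >= hi:
                assert cat == ">70%"
            else:
                assert cat == "30-70%"

    def test_two_bins_at_median(self):
        vals = pd.Series([5.0, 1.0, 3.0, 9.0, 7.0])
        disc = nc.discretize(vals, scheme=2)
        (cut,) = disc.cut_points
        assert cut == pytest.approx(5.0)
        assert list(disc.categories) == ["<50%", "<50%", "<50%", ">50%", ">50%"]

    def test_tie_with_lower_cut_goes_low(self):
        vals = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        disc = nc.discretize(vals, scheme=3)
        lo = disc.cut_points[0]
        assert disc.categories[vals == lo].eq("<30%").all()

    def test_constant_vector_degenerate(self):
        disc = nc.discretize(pd.Series([2.0, 2.0, 2.0]), scheme=3)
        assert disc.degenerate
        assert len(set(disc.categories)) == 1

    def test_missing_values_emit_no_category(self):
        vals = pd.Series([1.0, np.nan, 3.0, 4.0])
        disc = nc.discretize(vals, scheme=2)
        assert pd.isna(disc.categories.iloc[1])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            nc.discretize(pd.Series([np.nan, np.nan]))

    def test_table_discretization_drops_degenerate(self):
        env = pd.DataFrame(
            {"x": [0, 1, 2], "y": [0, 1, 0],
             "pH": [7.0, 8.0, 9.0], "flat": [1.0, 1.0, 1.0]},
            index=["a", "b", "c"],
        )
        cats, partition = nc.discretize_table(env, schemes={"pH": 2})
        assert "flat" not in cats.columns
        assert "x" not in cats.columns  # coordinates excluded
        row = partition.set_index("variable").loc["flat"]
        assert bool(row["degenerate"])
        assert partition.set_index("variable").loc["pH", "scheme"] == 2


# ---------------------------------------------------------------------------
# Transactions
# ---------------------------------------------------------------------------


class TestTransactions:
    def test_one_item_per_variable_and_cardinality_bound(self, synth32, catalog):
        records, env, _ = synth32
        cats, _ = nc.discretize_table(env)
        pres = nc.call_protein_presence(nc.compute_metrics(records, catalog), catalog)
        db = nc.build_transactions(cats, pres)
        assert db.n == 32
        k, m = len(cats.columns), len(catalog.proteins)
        for t in db.transactions:
            assert len(t) <= k + m
            seen_vars = [it.split("=", 1)[0] for it in t]
            assert len(seen_vars) == len(set(seen_vars))

    def test_missing_covariate_emits_no_item(self):
        cats = pd.DataFrame({"pH": ["<50%", np.nan]}, index=["a", "b"])
        db = nc.build_transactions(cats)
        assert db.transactions[0] == {"pH=<50%"}
        assert db.transactions[1] == frozenset()

    def test_presence_and_absence_items(self, micro, micro_metrics, catalog):
        _, env = micro
        cats, _ = nc.discretize_table(env)
        pres = nc.call_protein_presence(micro_metrics, catalog)
        db = nc.build_transactions(cats, pres)
        s1 = db.transactions[db.sample_ids.index("S1")]
        assert "NifDKH=Present" in s1 and "Hzs=Absent" in s1
        db2 = nc.build_transactions(cats, pres, absence_items=False)
        s1b = db2.transactions[db2.sample_ids.index("S1")]
        assert "Hzs=Absent" not in s1b and "NifDKH=Present" in s1b

    def test_basket_export(self, tmp_path):
        db = TransactionDB([frozenset({"b=1", "a=2"})], ["s1"])
        p = tmp_path / "baskets.txt"
        nc.write_baskets(db, p)
        assert p.read_text() == "s1\ta=2,b=1\n"


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------


class TestApriori:
    def test_worked_four_transaction_example(self):
        db = TransactionDB(
            [frozenset("AB"), frozenset("AB"), frozenset("A"), frozenset("B")],
            list("wxyz"),
        )
        freq = nc.apriori(db, 0.5)
        assert freq == {
            frozenset("A"): 0.75,
            frozenset("B"): 0.75,
            frozenset("AB"): 0.5,
        }

    def test_min_support_one_keeps_universal_sets_only(self):
        db = TransactionDB(
            [frozenset("AB"), frozenset("ABC"), frozenset("AB")], list("xyz")
        )
        freq = nc.apriori(db, 1.0)
        assert set(freq) == {frozenset("A"), frozenset("B"), frozenset("AB")}

    def test_empty_alphabet(self):
        db = TransactionDB([frozenset(), frozenset()], ["a", "b"])
        assert nc.apriori(db, 0.5) == {}

    def test_invalid_min_support(self):
        db = TransactionDB([frozenset("A")], ["a"])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                nc.apriori(db, bad)

    def test_max_len_caps_itemset_size(self):
        db = TransactionDB([frozenset("ABCD")] * 4, list("wxyz"))
        freq = nc.apriori(db, 0.5, max_len=2)
        assert max(len(s) for s in freq) == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.1, 0.25, 0.5]))
    def test_matches_exhaustive_enumeration(self, seed, min_support):
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        fast = nc.apriori(db, min_support)
        slow = brute_force_frequent(db, min_support)
        assert set(fast) == set(slow)
        for s in fast:
            assert fast[s] == pytest.approx(slow[s], abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_anti_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        freq = nc.apriori(db, 0.2)
        for s in freq:
            for it in s:
                assert (s - {it}) in freq or len(s) == 1


# ---------------------------------------------------------------------------
# Rule generation
# ---------------------------------------------------------------------------


class TestRuleGeneration:
    def _mine(self, db, min_support, min_confidence, **kw):
        freq = nc.apriori(db, min_support)
        return nc.generate_rules(freq, db, min_confidence, **kw)

    def test_support_confidence_lift_worked_example(self):
        # 7 of 32 samples carry both items; all antecedent carriers have the
        # consequent; consequent alone in 14 samples.
        ant, con = "Fungi=>70%", "NxrAB=Present"
        txs = (
            [frozenset({ant, con})] * 7
            + [frozenset({con})] * 7
            + [frozenset()] * 18
        )
        db = TransactionDB(txs, [f"s{i}" for i in range(32)])
        rules = self._mine(db, 0.1, 0.9)
        rule = next(
            r for r in rules
            if r.antecedent == {ant} and r.consequent == {con}
        )
        assert round(rule.support, 2) == 0.22  # 7/32
        assert rule.confidence == pytest.approx(1.0)
        assert rule.lift == pytest.approx(1 / (14 / 32))
        assert rule.n_antecedent == 7 and rule.n_both == 7

    def test_independent_items_have_lift_one(self):
        # A in half, B in half, jointly in a quarter: exact independence
        txs = (
            [frozenset("AB")] * 8 + [frozenset("A")] * 8
            + [frozenset("B")] * 8 + [frozenset()] * 8
        )
        db = TransactionDB(txs, [f"s{i}" for i in range(32)])
        rules = self._mine(db, 0.1, 0.4)
        rule = next(
            r for r in rules
            if r.antecedent == frozenset("A") and r.consequent == frozenset("B")
        )
        assert rule.lift == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rule_statistics_are_exact_ratios(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        rules = self._mine(db, 0.15, 0.5)
        for r in rules:
            supp_ant = db.support(r.antecedent)
            supp_con = db.support(r.consequent)
            supp_both = db.support(r.antecedent | r.consequent)
            assert r.support == pytest.approx(supp_both, abs=1e-15)
            assert r.support <= min(supp_ant, supp_con) + 1e-15
            assert r.support <= r.confidence + 1e-15
            assert r.confidence == pytest.approx(supp_both / supp_ant, abs=1e-12)
            assert r.lift * supp_con == pytest.approx(r.confidence, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_rule_set(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng, max_items=6, max_tx=15)
        rules = self._mine(db, 0.2, 0.6)
        got = {
            (r.antecedent, r.consequent, round(r.support, 12), round(r.confidence, 12))
            for r in rules
        }
        assert got == brute_force_rules(db, 0.2, 0.6)

    def test_consequent_filter_restricts_output(self):
        txs = [frozenset({"pH=<30%", "NosZ=Present"})] * 6 + [frozenset()] * 2
        db = TransactionDB(txs, [f"s{i}" for i in range(8)])
        rules = self._mine(
            db, 0.2, 0.5, consequent_filter=nc.single_protein_consequent(["NosZ"])
        )
        assert rules
        for r in rules:
            assert r.consequent == {"NosZ=Present"}

    def test_antecedent_length_cap(self):
        txs = [frozenset({"a=1", "b=1", "c=1", "d=1"})] * 4
        db = TransactionDB(txs, list("wxyz"))
        rules = self._mine(db, 0.5, 0.5, max_antecedent_len=1)
        assert rules and all(len(r.antecedent) == 1 for r in rules)

    def test_rules_sorted_by_lift_then_support(self, synth32, catalog):
        records, env, _ = synth32
        cats, _ = nc.discretize_table(env)
        pres = nc.call_protein_presence(nc.compute_metrics(records, catalog), catalog)
        db = nc.build_transactions(cats, pres)
        rules = nc.mine_rules(
            db, min_support=0.2, min_confidence=0.9,
            consequent_filter=nc.single_protein_consequent(catalog.proteins),
            max_antecedent_len=2,
        )
        lifts = [r.lift for r in rules]
        assert lifts == sorted(lifts, reverse=True) or all(
            a >= b - 1e-12 for a, b in zip(lifts, lifts[1:])
        )


class TestRuleGroupingAndExport:
    def _rules(self):
        txs = (
            [frozenset({"w=>70%", "NosZ=Present", "NorBC=Present"})] * 5
            + [frozenset({"NosZ=Present"})] * 3
            + [frozenset()] * 2
        )
        db = TransactionDB(txs, [f"s{i}" for i in range(10)])
        freq = nc.apriori(db, 0.2)
        return nc.generate_rules(
            freq, db, 0.8,
            consequent_filter=nc.single_protein_consequent(["NosZ", "NorBC"]),
        )

    def test_shared_consequent_shares_row(self):
        rules = self._rules()
        mat = nc.group_rules_by_consequent(rules)
        assert "NosZ=Present" in mat.index and "NorBC=Present" in mat.index
        cell = mat.loc["NorBC=Present", "w=>70%"]
        assert cell == (pytest.approx(0.5), pytest.approx(2.0))

    def test_empty_rule_list(self):
        mat = nc.group_rules_by_consequent([])
        assert mat.empty

    def test_multi_item_consequent_rejected(self):
        r = nc.AssociationRule(
            frozenset({"a=1"}), frozenset({"b=1", "c=1"}), 0.5, 1.0, 2.0, 1, 1
        )
        with pytest.raises(ValueError):
            nc.group_rules_by_consequent([r])

    def test_rule_tsv_export(self, tmp_path):
        rules = self._rules()
        p = tmp_path / "rules.tsv"
        nc.write_rules(rules, p)
        back = pd.read_csv(p, sep="\t")
        assert list(back.columns) == [
            "antecedent", "consequent", "support", "confidence", "lift",
            "n_antecedent", "n_both",
        ]
        assert len(back) == len(rules)
        assert (back["support"] <= back["confidence"] + 1e-15).all()
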