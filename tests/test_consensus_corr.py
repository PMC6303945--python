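"""Seed correlations, directional voting, CGCCS and trait statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drivernet.consensus_corr import (
    cgccs,
    correlation_long_table,
    directional_vote,
    seed_correlations,
    severity_group_tests,
    stratified_correlation,
    trait_correlation,
)
from drivernet.datatypes import TraitTable
from tests.conftest import make_expression


class TestSeedCorrelations:
    def test_duplicated_seed_gene_is_perfectly_correlated(self, rng):
        n = 60
        seed = rng.normal(size=n)
        vals = np.vstack([seed, seed, rng.normal(size=n)])
        expr = make_expression(vals, genes=["seed", "copy", "noise"])
        rec = seed_correlations(expr, "seed")
        copy = rec.set_index("gene").loc["copy"]
        assert copy["r"] == pytest.approx(1.0)
        assert copy["q"] < 1e-10 and copy["sign"] == "+"

    def test_negated_gene_has_negative_sign(self, rng):
        n = 60
        seed = rng.normal(size=n)
        expr = make_expression(np.vstack([seed, -seed]), genes=["seed", "anti"])
        rec = seed_correlations(expr, "seed")
        anti = rec.set_index("gene").loc["anti"]
        assert anti["r"] == pytest.approx(-1.0)
        assert anti["sign"] == "-"

    def test_constant_seed_rejected(self, rng):
        expr = make_expression(
            np.vstack([np.ones(30), rng.normal(size=30)]), genes=["seed", "g"]
        )
        with pytest.raises(ValueError, match="constant"):
            seed_correlations(expr, "seed")

    def test_bh_null_rate_controlled(self):
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = make_expression(r.normal(size=(200, 80)))
            rec = seed_correlations(expr, "g0")
            fracs.append(rec["significant"].mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 3 * se


def records_fixture():
    """Hand-built per-dataset significance records for one gene set."""
    rows = []
    #             dataset, gene, sig, sign
    layout = [
        *[(f"d{i}", "gA", True, "+") for i in range(6)],
        ("d6", "gA", True, "-"),
        ("d7", "gA", False, "+"),
        *[(f"d{i}", "gB", False, "+") for i in range(8)],
        *[(f"d{i}", "gC", True, "-") for i in range(5)],  # measured in 5 only
    ]
    for ds, gene, sig, sign in layout:
        rows.append(
            {"dataset": ds, "gene": gene, "r": 0.5 if sign == "+" else -0.5,
             "p": 0.001 if sig else 0.5, "q": 0.01 if sig else 0.6,
             "significant": sig, "sign": sign}
        )
    return pd.DataFrame(rows)


class TestDirectionalVote:
    def test_counts_match_fixture(self):
        tally = directional_vote(records_fixture()).set_index("gene")
        assert tally.loc["gA", "c_pos"] == 6
        assert tally.loc["gA", "c_neg"] == 1
        assert tally.loc["gA", "frequency"] == 6
        assert tally.loc["gB", "c_pos"] == 0 and tally.loc["gB", "c_neg"] == 0
        assert tally.loc["gC", "n_datasets"] == 5
        assert tally.loc["gC", "c_pos"] + tally.loc["gC", "c_neg"] <= 5

    def test_dataset_order_invariance(self):
        rec = records_fixture()
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            directional_vote(rec), directional_vote(shuffled)
        )

    def test_duplicate_records_rejected(self):
        rec = records_fixture()
        dup = pd.concat([rec, rec.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            directional_vote(dup)


class TestCgccs:
    def test_weakest_threshold_collects_any_significant(self):
        tally = directional_vote(records_fixture())
        net = cgccs(tally, 1, 8)
        assert net.genes == {"gA", "gC"}

    def test_nesting(self, rng):
        tally = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(30)],
                "c_pos": rng.integers(0, 9, 30),
                "c_neg": rng.integers(0, 9, 30),
            }
        )
        tally["n_datasets"] = 8
        tally["frequency"] = tally[["c_pos", "c_neg"]].max(axis=1)
        sizes = [len(cgccs(tally, n, 8).genes) for n in range(1, 9)]
        members = [cgccs(tally, n, 8).genes for n in range(1, 9)]
        assert all(b <= a for a, b in zip(members, members[1:]))
        assert all(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:]))

    def test_matches_bruteforce_on_fixture(self, rng):
        tally = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "c_pos": rng.integers(0, 9, 10),
                "c_neg": rng.integers(0, 9, 10),
            }
        )
        tally["n_datasets"] = 8
        tally["frequency"] = tally[["c_pos", "c_neg"]].max(axis=1)
        for n in range(1, 9):
            expected = {
                row.gene
                for row in tally.itertuples()
                if max(row.c_pos, row.c_neg) >= n
            }
            assert cgccs(tally, n, 8).genes == expected

    def test_ambiguous_sign_marked(self):
        tally = pd.DataFrame(
            {"gene": ["g"], "c_pos": [3], "c_neg": [3], "n_datasets": [8],
             "frequency": [3]}
        )
        net = cgccs(tally, 3, 8)
        assert list(net.members["sign"]) == ["ambiguous"]

    def test_out_of_range_threshold_rejected(self):
        tally = directional_vote(records_fixture())
        with pytest.raises(ValueError, match="outside"):
            cgccs(tally, 9, 8)

    def test_long_table_annotations(self):
        rec = records_fixture()
        table = correlation_long_table(rec, all_genes=["gA", "gB", "gC", "gD"])
        gd = table[(table["gene"] == "gD")]
        assert (gd["annotation"] == "na").all()
        assert set(table["annotation"]) <= {"**", "*", "ns", "na"}


def traits_fixture(n, rng, trait_vals=None):
    table = pd.DataFrame(index=[f"s{i}" for i in range(n)])
    table["CDR"] = trait_vals if trait_vals is not None else rng.integers(0, 6, n).astype(float)
    return TraitTable(table)


class TestTraitCorrelation:
    def test_exact_copy_has_unit_correlation(self, rng):
        n = 30
        gene = rng.normal(size=n)
        expr = make_expression(gene[None, :], genes=["g"])
        table = pd.DataFrame({"PLQ_Mn": gene - gene.min()}, index=expr.samples)
        out = trait_correlation(expr, TraitTable(table), ["g"], ["PLQ_Mn"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_trait_rejected(self, rng):
        n = 20
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng, trait_vals=np.full(n, 2.0))
        with pytest.raises(ValueError, match="constant"):
            trait_correlation(expr, traits, ["g"], ["CDR"])

    def test_too_few_complete_pairs_rejected(self, rng):
        n = 10
        vals = np.full(n, np.nan)
        vals[:2] = [1.0, 2.0]
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng, trait_vals=vals)
        with pytest.raises(ValueError, match="complete pairs"):
            trait_correlation(expr, traits, ["g"], ["CDR"])

    def test_generator_loading_closed_form(self):
        # trait score = 0.6 z + e (unit noise), so r = 0.6/sqrt(1.36)
        r_ = np.random.default_rng(5)
        n = 4000
        z = r_.normal(size=n)
        score = 0.6 * z + r_.normal(size=n)
        expr = make_expression(z[None, :], genes=["g"])
        table = pd.DataFrame({"PLQ_Mn": score - score.min()},
                             index=[f"s{i}" for i in range(n)])
        out = trait_correlation(expr, TraitTable(table), ["g"], ["PLQ_Mn"])
        rho = 0.6 / np.sqrt(1.36)
        assert abs(out["r"].iloc[0] - rho) < 3 * (1 - rho**2) / np.sqrt(n)

    def test_spearman_available(self, rng):
        n = 50
        gene = rng.normal(size=n)
        expr = make_expression(gene[None, :], genes=["g"])
        traits = traits_fixture(n, rng)
        out = trait_correlation(expr, traits, ["g"], ["CDR"], method="spearman")
        assert "r" in out and len(out) == 1


class TestStratified:
    def test_identical_generators_give_similar_r(self):
        r_ = np.random.default_rng(7)
        n = 400
        z = r_.normal(size=n)
        score = 0.6 * z + r_.normal(size=n)
        expr = make_expression(z[None, :], genes=["g"])
        table = pd.DataFrame({"PLQ_Mn": score - score.min()},
                             index=[f"s{i}" for i in range(n)])
        traits = TraitTable(table)
        strata = {
            "A": [f"s{i}" for i in range(0, n, 2)],
            "B": [f"s{i}" for i in range(1, n, 2)],
        }
        out = stratified_correlation(expr, traits, "g", "PLQ_Mn", strata)
        assert out["defined"].all()
        rA, rB = out.set_index("stratum")["r"]
        assert abs(rA - rB) < 4 / np.sqrt(n // 2)

    def test_loaded_versus_null_stratum(self):
        hits = 0
        for seed in range(10):
            r_ = np.random.default_rng(seed)
            n = 200
            z = r_.normal(size=2 * n)
            score = np.concatenate([
                0.6 * z[:n] + r_.normal(size=n),   # loaded stratum
                r_.normal(size=n),                  # null stratum
            ])
            expr = make_expression(z[None, :], genes=["g"],
                                   samples=[f"s{i}" for i in range(2 * n)])
            traits = TraitTable(pd.DataFrame(
                {"PLQ_Mn": score - score.min()}, index=expr.samples))
            strata = {"loaded": expr.samples[:n], "null": expr.samples[n:]}
            out = stratified_correlation(expr, traits, "g", "PLQ_Mn", strata)
            r = out.set_index("stratum")["r"]
            hits += abs(r["loaded"]) > abs(r["null"])
        assert hits >= 9

    def test_singleton_stratum_undefined(self, rng):
        n = 20
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng)
        out = stratified_correlation(
            expr, traits, "g", "CDR",
            {"big": expr.samples[:-1], "single": expr.samples[-1:]},
        )
        row = out.set_index("stratum").loc["single"]
        assert not row["defined"] and np.isnan(row["r"])

    def test_overlapping_strata_rejected(self, rng):
        n = 10
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng)
        with pytest.raises(ValueError, match="overlap"):
            stratified_correlation(
                expr, traits, "g", "CDR",
                {"a": expr.samples[:6], "b": expr.samples[4:]},
            )


class TestSeverityGroups:
    def test_pair_count_is_k_choose_2(self, rng):
        n = 120
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng, trait_vals=np.repeat([0, 1, 2, 3.0], n // 4))
        out = severity_group_tests(expr, traits, "g", "CDR")
        assert len(out) == 4 * 3 // 2

    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(150):
            r_ = np.random.default_rng(seed)
            x = r_.normal(size=40)
            expr = make_expression(x[None, :], genes=["g"])
            traits = traits_fixture(40, r_, trait_vals=np.repeat([0.0, 1.0], 20))
            out = severity_group_tests(expr, traits, "g", "CDR")
            pvals.append(out["p"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_for_unit_shift(self):
        hits = 0
        for seed in range(20):
            r_ = np.random.default_rng(seed)
            x = np.concatenate([r_.normal(0, 1, 50), r_.normal(1.0, 1, 50)])
            expr = make_expression(x[None, :], genes=["g"])
            traits = traits_fixture(100, r_, trait_vals=np.repeat([0.0, 1.0], 50))
            out = severity_group_tests(expr, traits, "g", "CDR")
            hits += out["p"].iloc[0] < 0.001
        assert hits >= 19  # >= 95% power

    def test_degenerate_grouping_rejected(self, rng):
        n = 10
        expr = make_expression(rng.normal(size=(1, n)), genes=["g"])
        traits = traits_fixture(n, rng, trait_vals=np.full(n, 1.0))
        with pytest.raises(ValueError, match="2 groups"):
            severity_group_tests(expr, traits, "g", "CDR")
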