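"""Copy-number / expression concurrency calling and target nomination."""

import numpy as np
import pandas as pd
import pytest

from mpnstkit.containers import ExpressionMatrix
from mpnstkit.copynumber import GeneCNMatrix
from mpnstkit.errors import ArgumentError
from mpnstkit.integration import (IntegrationConfig, call_concurrency,
                                  concurrent_genes, geneset_concurrency_enrichment,
                                  intersect_candidates, nominate_loss_targets)


def toy_gene_cn(n_samples=24, seed=0):
    """Three genes: strong dosage gene, under-powered gene (4 gains), weak-shift gene."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_samples)]
    genes = ["strong", "rare", "weak"]
    cont = pd.DataFrame(2.0, index=genes, columns=samples)
    calls = pd.DataFrame("neutral", index=genes, columns=samples)
    loh = pd.DataFrame(False, index=genes, columns=samples)
    gain_strong = samples[:10]
    gain_rare = samples[:4]
    gain_weak = samples[:10]
    for g, cols in [("strong", gain_strong), ("rare", gain_rare), ("weak", gain_weak)]:
        cont.loc[g, cols] = 3.0
        calls.loc[g, cols] = "gain"
    expr = pd.DataFrame(rng.normal(7.0, 0.15, size=(3, n_samples)),
                        index=genes, columns=samples)
    expr.loc["strong", gain_strong] += 1.5
    expr.loc["rare", gain_rare] += 1.5
    expr.loc["weak", gain_weak] += 0.3  # significant but below the 0.5 magnitude rule
    em = ExpressionMatrix(expr, pd.Series("tumour", index=samples))
    gcn = GeneCNMatrix(continuous=cont, calls=calls, loh=loh,
                       ploidy=pd.Series(2.0, index=samples))
    return gcn, em


class TestConcurrencyCalling:
    def test_thresholds_applied_as_specified(self):
        gcn, em = toy_gene_cn()
        calls = call_concurrency(gcn, em, IntegrationConfig(expr_variance_min=0.0))
        by_gene = calls.set_index(["gene", "direction"])
        # strong dosage gene passes gain_up
        assert bool(by_gene.loc[("strong", "gain_up"), "passed"])
        # gene with only 4 aberrant samples is not evaluated at all
        assert "rare" not in set(calls["gene"])
        # significant but small (0.4) median shift fails the magnitude rule
        assert not bool(by_gene.loc[("weak", "gain_up"), "passed"])

    def test_no_neutral_samples_skips_gene_with_reason(self):
        gcn, em = toy_gene_cn()
        gcn.calls.loc["strong"] = "gain"
        calls = call_concurrency(gcn, em, IntegrationConfig(expr_variance_min=0.0))
        assert "strong" in calls.attrs["skipped"]

    def test_planted_recovery_on_default_cohort(self, default_cohort, default_gene_cn):
        calls = call_concurrency(default_gene_cn, default_cohort.expression)
        passed = set(concurrent_genes(calls))
        evaluated = set(calls["gene"])
        dosage = set(default_cohort.truth.dosage_genes)
        sens = len(passed & dosage) / len(evaluated & dosage)
        non = evaluated - dosage
        spec = 1 - len(passed & non) / len(non)
        assert sens >= 0.8 and spec >= 0.95

    def test_requires_shared_samples(self, default_cohort, default_gene_cn):
        with pytest.raises(ArgumentError):
            call_concurrency(default_gene_cn, default_cohort.expression,
                             samples=default_cohort.expression.tumour_samples()[:5])


def calls_frame(proportions: dict[str, tuple[int, int]]) -> tuple[pd.DataFrame, dict]:
    """Build a concurrency-call table and set collection with given k/m per set."""
    rows, sets = [], {}
    gid = 0
    for name, (k, m) in proportions.items():
        members = []
        for i in range(m):
            g = f"{name}_g{gid}"
            gid += 1
            members.append(g)
            rows.append({"gene": g, "direction": "gain_up", "passed": i < k})
        sets[name] = members
    return pd.DataFrame(rows), sets


class TestSetConcurrencyEnrichment:
    def test_hand_computed_fisher_against_median(self):
        calls, sets = calls_frame({"big": (6, 10), "a": (1, 10), "b": (1, 10)})
        table = geneset_concurrency_enrichment(calls, sets).set_index("gene_set")
        assert table.loc["big", "proportion"] == pytest.approx(0.6)
        assert table["median_proportion"].iloc[0] == pytest.approx(0.1)
        # [6,4; 1,9] one-sided hypergeometric p = 2220/77520
        assert table.loc["big", "p"] == pytest.approx(2220 / 77520, rel=1e-9)
        assert table.loc["big", "p"] < 0.05 and not table.loc["big", "flagged"]

    def test_uniform_proportions_flag_nothing(self):
        calls, sets = calls_frame({"a": (2, 10), "b": (2, 10), "c": (2, 10)})
        table = geneset_concurrency_enrichment(calls, sets)
        assert not table["flagged"].any()

    def test_zero_concurrent_set_has_p_one(self):
        calls, sets = calls_frame({"none": (0, 10), "a": (3, 10), "b": (3, 10)})
        table = geneset_concurrency_enrichment(calls, sets).set_index("gene_set")
        assert table.loc["none", "p"] == pytest.approx(1.0)

    def test_needs_three_sets(self):
        calls, sets = calls_frame({"a": (1, 5), "b": (1, 5)})
        with pytest.raises(ArgumentError):
            geneset_concurrency_enrichment(calls, sets)


class TestCandidateIntersection:
    def test_toy_intersection(self):
        freq = pd.Series({"A": 0.5, "B": 0.25, "C": 0.15, "D": 0.6})
        out = intersect_candidates(["A", "B", "C"], ["B", "C", "D"], freq)
        assert out["candidates"] == ["B"]
        assert out["venn"]["de&concurrent"] == 2

    def test_boundary_frequency_excluded(self):
        freq = pd.Series({"B": 0.20})
        out = intersect_candidates(["B"], ["B"], freq)
        assert out["candidates"] == []

    def test_empty_input_and_idempotence(self):
        freq = pd.Series({"A": 0.9, "B": 0.9})
        assert intersect_candidates([], ["A"], freq)["candidates"] == []
        once = intersect_candidates(["A", "B"], ["A", "B"], freq)["candidates"]
        again = intersect_candidates(once, once, freq)["candidates"]
        assert once == again == ["A", "B"]


class TestTargetNomination:
    def build(self, include_in_list=True, high_freq=0.8, seed=0):
        rng = np.random.default_rng(seed)
        high = [f"H{i}" for i in range(10)]
        low = [f"L{i}" for i in range(10)]
        samples = high + low
        genes = ["target", "bystander"]
        cont = pd.DataFrame(2.0, index=genes, columns=samples)
        calls = pd.DataFrame("neutral", index=genes, columns=samples)
        loh = pd.DataFrame(False, index=genes, columns=samples)
        n_high = int(round(high_freq * len(high)))
        calls.loc["target", high[:n_high]] = "loss"
        calls.loc["target", low[:1]] = "loss"
        expr = pd.DataFrame(rng.normal(7, 0.3, size=(2, 20)), index=genes,
                            columns=samples)
        em = ExpressionMatrix(expr, pd.Series("tumour", index=samples))
        gcn = GeneCNMatrix(continuous=cont, calls=calls, loh=loh,
                           ploidy=pd.Series(2.0, index=samples))
        survival = pd.DataFrame({"sample": samples,
                                 "time": rng.uniform(0.5, 5.0, size=20),
                                 "event": rng.integers(0, 2, size=20)})
        cc = pd.DataFrame([{"gene": "target", "direction": "loss_down", "passed": True}])
        cancer = ["target"] if include_in_list else []
        return high, low, gcn, em, survival, cancer, cc

    def test_planted_target_nominated(self):
        high, low, gcn, em, surv, cancer, cc = self.build()
        out = nominate_loss_targets(high, low, gcn, em, surv, cancer, cc)
        row = out.set_index("gene").loc["target"]
        assert row["nominated"] and row["freq_diff"] == pytest.approx(0.7)
        assert not out.set_index("gene").loc["bystander", "nominated"]

    def test_gene_off_cancer_list_not_nominated(self):
        high, low, gcn, em, surv, cancer, cc = self.build(include_in_list=False)
        out = nominate_loss_targets(high, low, gcn, em, surv, cancer, cc)
        assert not out["nominated"].any()

    def test_exact_forty_percent_difference_excluded(self):
        high, low, gcn, em, surv, cancer, cc = self.build(high_freq=0.5)
        # freq_high 0.5, freq_low 0.1 -> diff 0.4 exactly: strict > excludes
        out = nominate_loss_targets(high, low, gcn, em, surv, cancer, cc)
        assert not out.set_index("gene").loc["target", "nominated"]

    def test_small_stratum_rejected(self):
        high, low, gcn, em, surv, cancer, cc = self.build()
        with pytest.raises(ArgumentError):
            nominate_loss_targets(high[:2], low, gcn, em, surv, cancer, cc)
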