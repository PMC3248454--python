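import numpy as np
import pandas as pd
import pytest

import kinscreen as ks
from kinscreen.estimators import PairEstimates
from kinscreen.relationships import (
    CallThresholds,
    build_pedigrees,
    call_pairs,
    classify_pair,
    reconcile_call,
    summarize,
)

from conftest import FAMILY_SEXES, quoted_family_calls


def pe(kinship=0.0, ibs0=0.05, z0=1.0, z1=0.0, z2=0.0, pi=0.0, ids=("a", "b")):
    return PairEstimates(
        id_i=ids[0], id_j=ids[1], kinship=kinship, ibs0_frac=ibs0,
        z0=z0, z1=z1, z2=z2, pi_hat=pi, n_valid=50_000,
    )


class TestKinshipBands:
    @pytest.mark.parametrize(
        "kinship,degree",
        [
            (0.40, "MZ"),
            (0.354, "first"),      # band edge belongs to first, not MZ
            (0.177, "first"),      # inclusive lower bound, kept conservative
            (0.176, "second"),
            (0.0884, "second"),    # inclusive lower bound
            (0.088, "unrelated"),
            (-0.05, "unrelated"),
        ],
    )
    def test_band_edges(self, kinship, degree):
        assert classify_pair(pe(kinship=kinship)).degree == degree

    def test_po_fs_split_by_ibs0(self):
        assert classify_pair(pe(kinship=0.25, ibs0=0.001)).subtype == "PO"
        assert classify_pair(pe(kinship=0.25, ibs0=0.02)).subtype == "FS"


class TestReconciliation:
    def test_promote_second_to_fs_above_049(self):
        e = pe(kinship=0.15, ibs0=0.02, z0=0.2, z1=0.58, z2=0.22, pi=0.495)
        call = reconcile_call(classify_pair(e), e)
        assert (call.degree, call.subtype) == ("first", "FS")
        assert call.rule_fired == "second_promoted_fs"

    def test_keep_second_near_045(self):
        e = pe(kinship=0.15, ibs0=0.02, z0=0.2, z1=0.7, z2=0.1, pi=0.45)
        call = reconcile_call(classify_pair(e), e)
        assert call.degree == "second"
        assert call.rule_fired == "kinship_band_default"

    def test_demote_fs_below_041(self):
        e = pe(kinship=0.2, ibs0=0.02, z0=0.3, z1=0.6, z2=0.1, pi=0.40)
        call = reconcile_call(classify_pair(e), e)
        assert call.degree == "second"
        assert call.rule_fired == "fs_demoted_second"

    def test_mz_confirmed_above_099(self):
        e = pe(kinship=0.49, ibs0=0.0, z0=0.0, z1=0.0, z2=1.0, pi=0.995)
        call = reconcile_call(classify_pair(e), e)
        assert (call.degree, call.rule_fired) == ("MZ", "mz_ibd_confirmed")

    def test_contradictory_mz_degraded_not_raised(self):
        e = pe(kinship=0.40, ibs0=0.02, z0=0.3, z1=0.5, z2=0.2, pi=0.45)
        call = reconcile_call(classify_pair(e), e)
        assert call.degree == "first"
        assert call.inconsistent

    def test_po_and_fs_confirmation(self):
        po = pe(kinship=0.25, ibs0=0.0, z0=0.001, z1=0.99, z2=0.009, pi=0.5045)
        assert reconcile_call(classify_pair(po), po).rule_fired == "po_ibd_confirmed"
        fs = pe(kinship=0.25, ibs0=0.02, z0=0.25, z1=0.5, z2=0.25, pi=0.5)
        assert reconcile_call(classify_pair(fs), fs).rule_fired == "fs_ibd_confirmed"

    def test_fs_signature_below_band_recorded_as_second(self):
        e = pe(kinship=0.07, ibs0=0.02, z0=0.2, z1=0.5, z2=0.3, pi=0.55)
        call = reconcile_call(classify_pair(e), e)
        assert call.degree == "second"
        assert call.rule_fired == "below_band_recorded_second"

    def test_order_independent_across_pairs(self):
        rng = np.random.default_rng(0)
        rows = []
        for k in range(30):
            z0, z1 = rng.random(), rng.random()
            s = max(z0 + z1, 1.0)
            z0, z1 = z0 / s, z1 / s
            z2 = 1 - z0 - z1
            rows.append(
                dict(id_i=f"a{k}", id_j=f"b{k}", n_valid=1000,
                     kinship=rng.uniform(-0.1, 0.5), ibs0_frac=rng.uniform(0, 0.1),
                     z0=z0, z1=z1, z2=z2, pi_hat=z2 + 0.5 * z1)
            )
        df = pd.DataFrame(rows)
        out1 = call_pairs(df)
        out2 = call_pairs(df.iloc[::-1].reset_index(drop=True))
        merged = out1.merge(out2, on=["id_i", "id_j"], suffixes=("_a", "_b"))
        assert (merged["degree_a"] == merged["degree_b"]).all()
        assert (merged["rule_fired_a"] == merged["rule_fired_b"]).all()

    def test_cross_subset_subband_pair_filtered(self):
        df = pd.DataFrame(
            [dict(id_i="a", id_j="b", n_valid=1000, kinship=0.03, ibs0_frac=0.02,
                  z0=0.2, z1=0.5, z2=0.3, pi_hat=0.55)]
        )
        out = call_pairs(
            df, source_subset={"a": "S1", "b": "S2"},
        )
        assert out.loc[0, "degree"] == "unrelated"
        assert out.loc[0, "rule_fired"] == "cross_subset_filtered"


class TestBuildPedigrees:
    def test_worked_family_two_trios_one_duo(self):
        rep = build_pedigrees(quoted_family_calls(), FAMILY_SEXES)
        assert len(rep.trios) == 2
        children = sorted(t["child"] for t in rep.trios)
        assert children == ["45", "48"]
        for t in rep.trios:
            assert {t["father"], t["mother"]} == {"49", "50"}
            assert t["father"] == "50" and t["mother"] == "49"
        assert rep.duos == [("42", "49")]
        assert rep.inconsistencies == []
        assert set(rep.grandparental) == {("42", "45"), ("42", "48")}
        assert rep.components == [["42", "45", "48", "49", "50"]]

    def test_single_po_pair_is_a_duo(self):
        calls = quoted_family_calls().iloc[[4]].reset_index(drop=True)  # 42-49
        rep = build_pedigrees(calls, FAMILY_SEXES)
        assert rep.trios == []
        assert rep.duos == [("42", "49")]
        assert rep.inconsistencies == []

    def test_same_sex_candidate_parents_rejected_and_flagged(self):
        calls = pd.DataFrame(
            [
                dict(id_i="c", id_j="p1", degree="first", subtype="PO",
                     rule_fired="x", cross_population=False, cross_subset=False,
                     inconsistent=False),
                dict(id_i="c", id_j="p2", degree="first", subtype="PO",
                     rule_fired="x", cross_population=False, cross_subset=False,
                     inconsistent=False),
            ]
        )
        rep = build_pedigrees(calls, {"c": "female", "p1": "male", "p2": "male"})
        assert rep.trios == []
        assert len(rep.duos) == 2
        assert any("share declared sex" in s for s in rep.inconsistencies)

    def test_fs_pairs_with_conflicting_parents_flagged(self):
        rows = []

        def add(a, b, subtype):
            rows.append(
                dict(id_i=a, id_j=b, degree="first", subtype=subtype,
                     rule_fired="x", cross_population=False, cross_subset=False,
                     inconsistent=False)
            )

        # two children with PO links to disjoint parent pairs but called FS
        add("c1", "f1", "PO"); add("c1", "m1", "PO")
        add("c2", "f2", "PO"); add("c2", "m2", "PO")
        add("c1", "c2", "FS")
        sexes = {"f1": "male", "m1": "female", "f2": "male", "m2": "female",
                 "c1": "male", "c2": "female"}
        rep = build_pedigrees(pd.DataFrame(rows), sexes)
        assert len(rep.trios) == 2
        assert any("different parent" in s for s in rep.inconsistencies)


class TestSummarize:
    def test_worked_family_row(self):
        calls = quoted_family_calls()
        pops = {s: "MY-JH" for s in FAMILY_SEXES}
        table = summarize(calls, pops, sexes=FAMILY_SEXES)
        row = table[table["POP"] == "MY-JH"].iloc[0]
        assert (row["MZ"], row["Trios"], row["Duos"], row["FS"], row["2nd"]) == (
            0, 2, 1, 1, 2,
        )

    def test_no_calls_all_zero(self):
        calls = quoted_family_calls().iloc[:0]
        table = summarize(calls, {"a": "P1", "b": "P2"}, sexes={})
        assert (table[["MZ", "Trios", "Duos", "FS", "2nd"]].to_numpy() == 0).all()

    def test_cross_population_pair_counted_under_cross(self):
        calls = pd.DataFrame(
            [dict(id_i="a", id_j="b", degree="first", subtype="FS",
                  rule_fired="x", cross_population=True, cross_subset=False,
                  inconsistent=False)]
        )
        table = summarize(calls, {"a": "P1", "b": "P2"}, sexes={})
        assert table.set_index("POP").loc["*CROSS", "FS"] == 1
        assert table.set_index("POP").loc["P1", "FS"] == 0
        assert table.set_index("POP").loc["P2", "FS"] == 0
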