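"""Summary-statistic I/O, harmonization, LD pruning and MAF filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregmr.summary_data import (EXCL_ALLELE_MISMATCH, EXCL_PALINDROMIC,
                                 FormatError, HarmonizationError,
                                 ValidationError, filter_maf, harmonize,
                                 prune_ld, read_association_table,
                                 write_association_table)

from conftest import make_table, snp


class TestReadWrite:
    def test_round_trip_preserves_fields(self, tmp_path):
        table = make_table([
            {"rsid": "rs10", "beta": 0.123456789, "se": 0.0456, "eaf": 0.31},
            {"rsid": "rs11", "beta": -1.5e-4, "se": 1.0, "pvalue": 0.9},
            {"rsid": "rs12", "ea": "T", "oa": "C", "eaf": 0.999},
        ])
        path = tmp_path / "t.tsv"
        write_association_table(table, path)
        back = read_association_table(path, scale="log-odds")
        assert len(back) == 3
        for orig, new in zip(table.records, back.records):
            for field in ("rsid", "effect_allele", "other_allele", "eaf",
                          "beta", "se", "pvalue", "n"):
                assert getattr(orig, field) == getattr(new, field)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rsid\teffect_allele\tother_allele\teaf\tbeta\tse\n"
                        "rs1\tA\tG\t0.3\t0.1\t0.05\n")
        with pytest.raises(FormatError, match="pvalue"):
            read_association_table(path, scale="log-odds")

    def test_zero_se_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\tA\tG\t0.3\t0.1\t0.05\t0.01\t100\n"
            "rs2\tA\tG\t0.3\t0.1\t0\t0.01\t100\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_association_table(path, scale="log-odds")

    def test_lowercase_alleles_normalized(self, tmp_path):
        path = tmp_path / "lc.tsv"
        path.write_text(
            "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\ta\tg\t0.3\t0.1\t0.05\t0.01\t100\n")
        table = read_association_table(path, scale="log-odds")
        rec = table.records[0]
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")
        # and the normalized table round-trips unchanged
        out = tmp_path / "out.tsv"
        write_association_table(table, out)
        again = read_association_table(out, scale="log-odds")
        assert again.records[0] == rec

    def test_duplicate_rsids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_table([{"rsid": "rs1"}, {"rsid": "rs1"}])


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = make_table([{"beta": 0.2, "eaf": 0.3}])
        out = make_table([{"beta": 0.1, "eaf": 0.35}])
        h = harmonize(exp, out)
        row = h.retained().iloc[0]
        assert row["beta_outcome"] == 0.1
        assert row["eaf_outcome"] == 0.35

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_table([{"ea": "A", "oa": "G"}])
        out = make_table([{"ea": "G", "oa": "A", "beta": 0.10, "eaf": 0.30}])
        row = harmonize(exp, out).retained().iloc[0]
        assert row["beta_outcome"] == pytest.approx(-0.10)
        assert row["eaf_outcome"] == pytest.approx(0.70)

    def test_palindromic_mid_frequency_excluded(self):
        exp = make_table([{"ea": "A", "oa": "T", "eaf": 0.50}])
        out = make_table([{"ea": "A", "oa": "T", "eaf": 0.50}])
        h = harmonize(exp, out, palindromic_eaf_window=(0.42, 0.58))
        frame = h.frame
        assert frame["excluded"].iloc[0]
        assert frame["exclusion_reason"].iloc[0] == EXCL_PALINDROMIC

    def test_palindromic_outside_window_oriented_by_frequency(self):
        exp = make_table([{"ea": "A", "oa": "T", "eaf": 0.20}])
        out = make_table([{"ea": "A", "oa": "T", "eaf": 0.80, "beta": 0.3}])
        row = harmonize(exp, out).retained().iloc[0]
        assert row["beta_outcome"] == pytest.approx(-0.3)
        assert row["eaf_outcome"] == pytest.approx(0.20)

    def test_irreconcilable_alleles_flagged(self):
        exp = make_table([{"ea": "A", "oa": "G"}])
        out = make_table([{"ea": "A", "oa": "C"}])
        frame = harmonize(exp, out).frame
        assert frame["exclusion_reason"].iloc[0] == EXCL_ALLELE_MISMATCH

    def test_empty_intersection_errors(self):
        exp = make_table([{"rsid": "rs1"}])
        out = make_table([{"rsid": "rs2"}])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_non_overlap_dropped_and_counted(self):
        exp = make_table([{"rsid": "rs1"}, {"rsid": "rs2"}])
        out = make_table([{"rsid": "rs2"}, {"rsid": "rs3"}])
        h = harmonize(exp, out)
        assert h.frame["rsid"].tolist() == ["rs2"]
        assert h.n_dropped == 2

    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_double_swap_restores_original(self, beta, eaf):
        exp = make_table([{"ea": "A", "oa": "G", "eaf": 0.3}])
        out_swapped = make_table([{"ea": "G", "oa": "A", "beta": beta,
                                   "eaf": eaf}])
        once = harmonize(exp, out_swapped).retained().iloc[0]
        assert once["beta_outcome"] == pytest.approx(-beta)
        # harmonizing a table already on the exposure alleles is the inverse
        out_back = make_table([{"ea": "A", "oa": "G",
                                "beta": -beta, "eaf": 1 - eaf}])
        twice = harmonize(exp, out_back).retained().iloc[0]
        assert twice["beta_outcome"] == pytest.approx(-beta)
        assert twice["eaf_outcome"] == pytest.approx(1 - eaf)

    def test_idempotent_on_aligned_tables(self):
        exp = make_table([{"ea": "A", "oa": "G", "eaf": 0.3, "beta": 0.2},
                          {"rsid": "rs2", "ea": "C", "oa": "T", "eaf": 0.7,
                           "beta": -0.1}])
        out = make_table([{"ea": "G", "oa": "A", "eaf": 0.6, "beta": 0.1},
                          {"rsid": "rs2", "ea": "C", "oa": "T", "eaf": 0.72,
                           "beta": 0.05}])
        h1 = harmonize(exp, out)
        # rebuild the outcome table from the harmonized frame and re-harmonize
        realigned = make_table([
            {"rsid": r["rsid"], "ea": r["effect_allele"],
             "oa": r["other_allele"], "beta": r["beta_outcome"],
             "eaf": r["eaf_outcome"], "se": r["se_outcome"]}
            for _, r in h1.retained().iterrows()])
        h2 = harmonize(exp, realigned)
        pd.testing.assert_frame_equal(
            h1.retained()[["rsid", "beta_outcome", "eaf_outcome"]],
            h2.retained()[["rsid", "beta_outcome", "eaf_outcome"]])


def _brute_force_prune(records, ld, threshold):
    """Oracle: replay the greedy rule by explicit (pvalue, rsid) ordering."""
    chosen = []
    pool = sorted(records, key=lambda r: (r.pvalue, r.rsid))
    while pool:
        best = pool[0]
        chosen.append(best.rsid)
        pool = [r for r in pool[1:]
                if ld.loc[best.rsid, r.rsid] < threshold]
    return chosen


def _ld_frame(rsids, pairs):
    ld = pd.DataFrame(np.eye(len(rsids)), index=rsids, columns=rsids)
    for a, b, r2 in pairs:
        ld.loc[a, b] = ld.loc[b, a] = r2
    return ld


class TestPruneLd:
    def test_below_threshold_both_kept(self):
        t = make_table([{"rsid": "rs1", "pvalue": 1e-10},
                        {"rsid": "rs2", "pvalue": 1e-8}])
        ld = _ld_frame(["rs1", "rs2"], [("rs1", "rs2", 0.002)])
        assert prune_ld(t, ld, 0.01).rsids == ["rs1", "rs2"]

    def test_correlated_pair_keeps_smaller_pvalue(self):
        t = make_table([{"rsid": "rs1", "pvalue": 1e-8},
                        {"rsid": "rs2", "pvalue": 1e-10}])
        ld = _ld_frame(["rs1", "rs2"], [("rs1", "rs2", 0.5)])
        assert prune_ld(t, ld, 0.01).rsids == ["rs2"]

    def test_matches_oracle_on_correlated_triple(self):
        t = make_table([{"rsid": f"rs{i}", "pvalue": p} for i, p in
                        enumerate([1e-9, 1e-7, 1e-8, 1e-6], start=1)])
        ld = _ld_frame([f"rs{i}" for i in range(1, 5)],
                       [("rs1", "rs2", 0.8), ("rs2", "rs3", 0.6),
                        ("rs1", "rs3", 0.3)])
        result = prune_ld(t, ld, 0.01)
        oracle = _brute_force_prune(t.records, ld, 0.01)
        assert result.rsids == oracle == ["rs1", "rs4"]

    def test_missing_rsid_in_ld_errors(self):
        t = make_table([{"rsid": "rs1"}, {"rsid": "rs2"}])
        ld = _ld_frame(["rs1"], [])
        with pytest.raises(ValidationError, match="rs2"):
            prune_ld(t, ld, 0.01)

    @given(perm=st.permutations(range(5)))
    @settings(max_examples=30, deadline=None)
    def test_order_invariance(self, perm):
        base = [{"rsid": f"rs{i}", "pvalue": [1e-9, 1e-7, 1e-7, 1e-6, 0.5][i]}
                for i in range(5)]
        rsids = [f"rs{i}" for i in range(5)]
        ld = _ld_frame(rsids, [("rs0", "rs1", 0.9), ("rs1", "rs2", 0.9),
                               ("rs3", "rs4", 0.02)])
        ref = prune_ld(make_table(base), ld, 0.05).rsids
        shuffled = make_table([base[i] for i in perm])
        assert prune_ld(shuffled, ld, 0.05).rsids == ref


class TestFilterMaf:
    @pytest.mark.parametrize("eaf,kept", [
        (0.005, False),   # rare effect allele: removed at 1%
        (0.5, True),      # maximally common: always retained
        (0.995, False),   # rare other allele: symmetric removal
        (0.01, True),     # boundary: MAF == min_maf retained
    ])
    def test_maf_rule(self, eaf, kept):
        t = make_table([{"eaf": eaf}])
        out = filter_maf(t, min_maf=0.01)
        assert (len(out) == 1) is kept
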