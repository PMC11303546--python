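"""FST scans, absence enrichment, diagnostic screen, frequency change."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import beanpav as bp


def _meta(pools, statuses=None):
    n = len(pools)
    statuses = statuses or ["wild"] * n
    return pd.DataFrame(
        {
            "accession_id": [f"a{i}" for i in range(n)],
            "gene_pool": pools,
            "status": statuses,
            "subgroup": ["s"] * n,
            "latitude": [np.nan] * n,
            "longitude": [np.nan] * n,
        }
    )


class TestSingleLocusFst:
    def test_wild_vs_domesticated_worked_example(self):
        hw, ht, fst = bp.single_locus_fst(0.94, 0.25)
        assert hw == pytest.approx((2 * 0.94 * 0.06 + 2 * 0.25 * 0.75) / 2)
        assert ht == pytest.approx(2 * 0.595 * 0.405)
        assert fst == pytest.approx(0.49393, abs=1e-5)

    def test_fixed_difference_gives_one(self):
        assert bp.single_locus_fst(1.0, 0.0)[2] == pytest.approx(1.0)

    def test_equal_frequencies_give_zero(self):
        for p in (0.0, 0.25, 0.5, 1.0):
            assert bp.single_locus_fst(p, p)[2] == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(
        p1=st.floats(0, 1, allow_nan=False),
        p2=st.floats(0, 1, allow_nan=False),
    )
    def test_bounds_and_symmetry(self, p1, p2):
        fst_ab = bp.single_locus_fst(p1, p2)[2]
        fst_ba = bp.single_locus_fst(p2, p1)[2]
        assert 0.0 <= fst_ab <= 1.0
        assert fst_ab == pytest.approx(fst_ba, abs=1e-12)

    def test_matches_count_based_heterozygosity_oracle(self):
        """Direct recomputation from raw 0/1 columns agrees to 1e-12."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 40, size=2)
            col1 = rng.integers(0, 2, size=n1)
            col2 = rng.integers(0, 2, size=n2)
            p1 = col1.sum() / n1
            p2 = col2.sum() / n2
            # oracle: heterozygosities written out longhand
            h1 = 2 * p1 * (1 - p1)
            h2 = 2 * p2 * (1 - p2)
            hw = (h1 + h2) / 2
            pbar = (p1 + p2) / 2
            ht = 2 * pbar * (1 - pbar)
            expected = 0.0 if ht == 0 else (ht - hw) / ht
            assert bp.single_locus_fst(p1, p2)[2] == pytest.approx(
                expected, abs=1e-12
            )

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bp.single_locus_fst(1.1, 0.5)


class TestFstScan:
    def test_identically_fixed_genes_give_empty_table(self):
        m = pd.DataFrame(
            np.ones((5, 6), dtype=int),
            index=[f"g{i}" for i in range(5)],
            columns=[f"a{i}" for i in range(6)],
        )
        acc = _meta(["M"] * 3 + ["A"] * 3)
        with pytest.warns(UserWarning):
            table = bp.fst_scan(m, acc, {"gene_pool": "M"}, {"gene_pool": "A"})
        assert table.empty

    def test_fixed_difference_gene_ranks_first(self, rng):
        n_per = 10
        data = {}
        data["gfix"] = [1] * n_per + [0] * n_per
        for i in range(100):
            col = rng.integers(0, 2, size=2 * n_per)
            data[f"g{i}"] = col
        m = pd.DataFrame(data).T
        m.columns = [f"a{i}" for i in range(2 * n_per)]
        acc = _meta(["M"] * n_per + ["A"] * n_per)
        table = bp.fst_scan(m, acc, {"gene_pool": "M"}, {"gene_pool": "A"})
        assert table.loc["gfix", "fst"] == pytest.approx(1.0)
        assert bool(table.loc["gfix", "candidate"])

    def test_candidates_match_quantile_oracle(self, default_cohort):
        _, cohort = default_cohort
        table = bp.fst_scan(
            cohort.pav_truth, cohort.accessions,
            {"gene_pool": "M"}, {"gene_pool": "A"},
        )
        fst = np.sort(table["fst"].to_numpy())
        # hand-rolled linear-interpolation 95th percentile
        h = (len(fst) - 1) * 0.95
        lo = int(math.floor(h))
        threshold = fst[lo] + (h - lo) * (fst[min(lo + 1, len(fst) - 1)] - fst[lo])
        assert table["threshold_used"].iloc[0] == pytest.approx(threshold)
        expected = set(table.index[table["fst"] >= threshold])
        assert set(table.index[table["candidate"]]) == expected
        # scan/selection consistency
        assert len(expected) >= math.ceil(0.05 * len(table))
        non = table[~table["candidate"]]
        assert (non["fst"] < threshold).all()

    def test_overlapping_populations_raise(self, default_cohort):
        _, cohort = default_cohort
        with pytest.raises(ValueError):
            bp.fst_scan(
                cohort.pav_truth, cohort.accessions,
                {"gene_pool": "M"}, {"status": "wild"},
            )


class TestAbsenceEnrichment:
    def test_extreme_enrichment_attains_minimal_p(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        m = pd.DataFrame(
            rng.integers(0, 2, size=(200, 10)), index=genes,
            columns=[f"a{i}" for i in range(10)],
        )
        acc = _meta(["A"] * 10)
        cand = genes[:5]
        m.loc[cand] = 0  # absent everywhere in the focal pool
        fst_table = pd.DataFrame(
            {"candidate": [g in cand for g in genes]}, index=genes
        )
        res = bp.absence_enrichment(
            fst_table, m, {"gene_pool": "A"}, accessions=acc,
            n_boot=99, seed=1,
        )
        assert res.observed_absent_fraction == 1.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_empty_candidate_set_raises(self, small_matrix):
        fst_table = pd.DataFrame(
            {"candidate": False}, index=small_matrix.index
        )
        acc = _meta(["A"] * small_matrix.shape[1])
        acc["accession_id"] = small_matrix.columns
        with pytest.raises(ValueError):
            bp.absence_enrichment(fst_table, small_matrix, {"gene_pool": "A"},
                                  accessions=acc, n_boot=10, seed=0)


class TestDiagnosticScreen:
    def test_fixed_difference_p_matches_hypergeometric_enumeration(self):
        m = pd.DataFrame(
            {"g": [1] * 10 + [0] * 10}
        ).T
        m.columns = [f"a{i}" for i in range(20)]
        acc = _meta(["M"] * 10 + ["A"] * 10)
        table = bp.diagnostic_screen(m, acc, {"gene_pool": "M"}, {"gene_pool": "A"})
        expected = 2 / math.comb(20, 10)  # enumeration: only 2 tables as extreme
        assert table.loc["g", "fisher_p"] == pytest.approx(expected, rel=1e-9)
        assert bool(table.loc["g", "diagnostic"])
        assert bool(table.loc["g", "significant"])

    def test_identical_frequencies_not_significant(self):
        m = pd.DataFrame({"g": ([1] * 5 + [0] * 5) * 2}).T
        m.columns = [f"a{i}" for i in range(20)]
        acc = _meta(["M"] * 10 + ["A"] * 10)
        table = bp.diagnostic_screen(m, acc, {"gene_pool": "M"}, {"gene_pool": "A"})
        assert table.loc["g", "fisher_p"] == pytest.approx(1.0)
        assert not bool(table.loc["g", "significant"])

    def test_large_shift_significant_but_not_diagnostic(self):
        m = pd.DataFrame({"g": [1] * 20 + [1] * 10 + [0] * 10}).T
        m.columns = [f"a{i}" for i in range(40)]
        acc = _meta(["M"] * 20 + ["A"] * 20)
        table = bp.diagnostic_screen(m, acc, {"gene_pool": "M"}, {"gene_pool": "A"})
        assert bool(table.loc["g", "significant"])
        assert not bool(table.loc["g", "diagnostic"])

    def test_fdr_is_monotone_and_dominates_raw_p(self, default_cohort):
        _, cohort = default_cohort
        table = bp.diagnostic_screen(
            cohort.pav_truth, cohort.accessions,
            {"gene_pool": "M"}, {"gene_pool": "A"},
        )
        assert (table["fdr_q"] >= table["fisher_p"] - 1e-15).all()
        s = table.sort_values("fisher_p")
        assert (s["fdr_q"].diff().dropna() >= -1e-12).all()

    def test_recovers_planted_diagnostic_loci_exactly(self, default_cohort):
        _, cohort = default_cohort
        table = bp.diagnostic_screen(
            cohort.pav_truth, cohort.accessions,
            {"gene_pool": "M"}, {"gene_pool": "A"},
        )
        planted = set(
            cohort.locus_labels.index[cohort.locus_labels == "diagnostic"]
        )
        assert set(table.index[table["diagnostic"]]) == planted


class TestFrequencyChange:
    def _setup(self, rng, n_genes=60):
        n_w, n_d = 10, 10
        m = pd.DataFrame(
            rng.integers(0, 2, size=(n_genes, n_w + n_d)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{i}" for i in range(n_w + n_d)],
        )
        acc = _meta(["M"] * (n_w + n_d), ["wild"] * n_w + ["domesticated"] * n_d)
        return m, acc

    def test_printed_decline_example_is_lower_in_dom(self):
        assert bp.selection.relative_decline(0.94, 0.25) == pytest.approx(
            0.734, abs=1e-3
        )

    def test_equal_frequencies_are_not_lower_in_dom(self, rng):
        m, acc = self._setup(rng)
        # one gene with identical wild and domesticated frequency
        m.loc["geq"] = [1, 0] * 10
        res = bp.frequency_change_summary(
            m, acc, {"status": "wild"}, {"status": "domesticated"}, ["geq"]
        )
        assert res.candidate_lower_fraction == 0.0

    def test_strict_decline_is_counted(self, rng):
        m, acc = self._setup(rng)
        m.loc["gdec"] = [1] * 10 + [0] * 5 + [1] * 5
        res = bp.frequency_change_summary(
            m, acc, {"status": "wild"}, {"status": "domesticated"}, ["gdec"]
        )
        assert res.candidate_lower_fraction == 1.0

    def test_empty_candidates_raise(self, rng):
        m, acc = self._setup(rng)
        with pytest.raises(ValueError):
            bp.frequency_change_summary(
                m, acc, {"status": "wild"}, {"status": "domesticated"}, []
            )


def test_selector_string_and_dict_agree(default_cohort):
    _, cohort = default_cohort
    a = bp.select_accessions(cohort.accessions, "gene_pool=M,status=wild")
    b = bp.select_accessions(cohort.accessions, {"gene_pool": "M", "status": "wild"})
    assert a == b and len(a) > 0
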