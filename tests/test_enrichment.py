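"""Exact tests against independent oracles; tallying; usage comparison."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tcrforge.enrichment import (
    ContingencyTable2x2,
    bonferroni,
    cmh_test,
    compare_v_usage,
    fisher_exact_2x2,
    odds_ratio,
    run_enrichment,
    tally_position_aa,
)
from tcrforge.io import Clonotype, RepertoireLibrary
from tcrforge.numbering import build_framework_mask
from tcrforge.simulate import PlantedEffect, SyntheticConfig, generate_library


def fisher_two_sided_bruteforce(a, b, c, d):
    """Exact-rational enumeration of all tables with the observed margins:
    sum the point probabilities not exceeding the observed one."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def point(k):
        return (
            Fraction(math.comb(c1, k))
            * Fraction(math.comb(n - c1, r1 - k))
            / Fraction(math.comb(n, r1))
        )

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    p_obs = point(a)
    return float(sum(p for k in range(lo, hi + 1) if (p := point(k)) <= p_obs))


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_extreme_table_twice_point_probability(self):
        t = ContingencyTable2x2(10, 0, 0, 10)
        expected = fisher_two_sided_bruteforce(10, 0, 0, 10)
        assert fisher_exact_2x2(t) == pytest.approx(expected, rel=1e-12)
        # both extreme corners have equal point probability
        point = 1 / math.comb(20, 10)
        assert fisher_exact_2x2(t) == pytest.approx(2 * point, rel=1e-12)

    def test_asymmetric_table_vs_enumeration(self):
        t = ContingencyTable2x2(3, 7, 7, 3)
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_two_sided_bruteforce(3, 7, 7, 3), rel=1e-12
        )

    def test_exhaustive_small_margin_sweep(self):
        """Every table with row sums <= 12 matches rational enumeration."""
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        t = ContingencyTable2x2(a, r1 - a, c, r2 - c)
                        if t.degenerate:
                            continue
                        expected = fisher_two_sided_bruteforce(a, r1 - a, c, r2 - c)
                        assert fisher_exact_2x2(t) == pytest.approx(
                            expected, abs=1e-12
                        ), (a, r1 - a, c, r2 - c)

    def test_degenerate_margin_returns_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    def test_phenotype_swap_symmetry(self, a, b, c, d):
        """Swapping the phenotype rows leaves the two-sided p unchanged."""
        t = ContingencyTable2x2(a, b, c, d)
        swapped = ContingencyTable2x2(c, d, a, b)
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped), rel=1e-9)


class TestOddsRatio:
    def test_balanced(self):
        assert odds_ratio(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_arithmetic(self):
        assert odds_ratio(ContingencyTable2x2(80, 20, 20, 80)) == pytest.approx(16.0)

    def test_haldane_correction_on_zero_cell(self):
        value = odds_ratio(ContingencyTable2x2(10, 0, 0, 10))
        assert math.isfinite(value)
        assert value == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable2x2(0, 0, 5, 5))


def mh_chi_square_by_hand(a, b, c, d):
    """Single-table Mantel-Haenszel score chi-square, written out."""
    n = a + b + c + d
    expected_a = (a + b) * (a + c) / n
    variance = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    return (a - expected_a) ** 2 / variance


class TestCMH:
    def test_two_identical_null_strata(self):
        t = ContingencyTable2x2(5, 5, 5, 5)
        stat, p = cmh_test({"d1": t, "d2": t})
        assert stat == 0.0
        assert p == 1.0

    def test_single_stratum_equals_mh_chi_square(self):
        stat, _ = cmh_test({"d1": ContingencyTable2x2(80, 20, 20, 80)})
        assert stat == pytest.approx(mh_chi_square_by_hand(80, 20, 20, 80), rel=1e-12)

    def test_matches_statsmodels(self):
        """Cross-check against the independent StratifiedTable implementation."""
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        tables = {
            "d1": ContingencyTable2x2(18, 42, 7, 53),
            "d2": ContingencyTable2x2(30, 70, 21, 79),
        }
        arr = [[[t.a, t.b], [t.c, t.d]] for t in tables.values()]
        st_obj = sm_ct.StratifiedTable(np.array(arr).transpose(1, 2, 0))
        result = st_obj.test_null_odds(correction=False)
        stat, p = cmh_test(tables)
        assert stat == pytest.approx(float(result.statistic), rel=1e-10)
        assert p == pytest.approx(float(result.pvalue), rel=1e-10)

    def test_two_strata_vs_permutation_oracle(self):
        """CMH p agrees with a stratified permutation distribution.

        Margins fixed per stratum: the null distribution of the statistic
        follows from independent hypergeometric draws of each a_k.
        """
        tables = {
            "d1": ContingencyTable2x2(8, 2, 2, 8),
            "d2": ContingencyTable2x2(7, 3, 3, 7),
        }
        stat_obs, p_cmh = cmh_test(tables)
        rng = np.random.default_rng(0)
        n_perm = 10**6
        total = np.zeros(n_perm)
        expected = 0.0
        variance = 0.0
        for t in tables.values():
            n, r1, c1 = t.n, t.a + t.b, t.a + t.c
            total += rng.hypergeometric(c1, n - c1, r1, size=n_perm)
            expected += r1 * c1 / n
            variance += r1 * (n - r1) * c1 * (n - c1) / (n**2 * (n - 1))
        stat_perm = (total - expected) ** 2 / variance
        p_perm = float((stat_perm >= stat_obs * (1 - 1e-12)).mean())
        sigma = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        # the permutation null is discrete; allow the observed point mass
        point_mass = float(
            (np.abs(stat_perm - stat_obs) < 1e-9).mean()
        )
        assert abs(p_cmh - p_perm) <= 5 * sigma + point_mass + 0.01

    def test_stratum_relabeling_invariance(self):
        t1 = ContingencyTable2x2(8, 2, 2, 8)
        t2 = ContingencyTable2x2(7, 3, 3, 7)
        assert cmh_test({"x": t1, "y": t2}) == cmh_test({"y": t2, "x": t1})

    def test_all_degenerate_strata(self):
        stat, p = cmh_test({"d1": ContingencyTable2x2(0, 0, 5, 5)})
        assert (stat, p) == (0.0, 1.0)

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            cmh_test({})


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps,family,expected",
        [([0.04], 1, [0.04]), ([0.5], 10, [1.0]), ([0.01, 0.002], 5, [0.05, 0.01])],
    )
    def test_examples(self, ps, family, expected):
        assert bonferroni(ps, family) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.integers(1, 100))
    def test_never_decreases(self, ps, extra):
        family = len(ps) + extra
        adjusted = bonferroni(ps, family)
        assert all(adj >= p for adj, p in zip(adjusted, ps))
        assert all(adj <= 1.0 for adj in adjusted)

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


def _toy_library(n_dom_l, n_dom_other, n_weak_l, n_weak_other, donor="d1"):
    """alpha-chain library where position 96 carries L or the germline P."""
    clonos = []
    idx = 0
    for phenotype, n_l, n_other in (
        ("dominant", n_dom_l, n_dom_other),
        ("weak", n_weak_l, n_weak_other),
    ):
        for k in range(n_l + n_other):
            overrides = {96: "L"} if k < n_l else {}
            clonos.append(
                Clonotype(donor, phenotype, "alpha", "TRAV13-2", "TRAJ3",
                          f"CAAS{_cdr3_suffix(idx)}", framework_overrides=overrides)
            )
            idx += 1
    return RepertoireLibrary(clonos)


def _cdr3_suffix(i):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[(i // len(alphabet) ** k) % len(alphabet)] for k in range(4))


class TestTally:
    def test_two_identical_dominant_clonotypes(self, reference_germlines):
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV13-2", "TRAJ3", "CAASGG"),
            Clonotype("d1", "dominant", "alpha", "TRAV13-2", "TRAJ6", "CAASGA"),
            Clonotype("d1", "weak", "alpha", "TRAV13-2", "TRAJ6", "CAASGC"),
        ])
        mask = build_framework_mask(reference_germlines, "alpha")
        tally = tally_position_aa(lib, reference_germlines, mask)["alpha"]
        gene = reference_germlines.genes["TRAV13-2"]
        for pos in mask.positions:
            aa = gene.residue(pos)
            t = tally.table("d1", pos, aa)
            assert (t.a, t.c) == (2, 1)

    def test_counting_oracle_on_planted_table(self, reference_germlines):
        """Counts (80,20,20,80) from an 80%/20% planted split."""
        lib = _toy_library(80, 20, 20, 80)
        mask = build_framework_mask(reference_germlines, "alpha")
        tally = tally_position_aa(lib, reference_germlines, mask)["alpha"]
        t = tally.table("d1", 96, "L")
        assert (t.a, t.b, t.c, t.d) == (80, 20, 20, 80)

    def test_gap_positions_contribute_nothing(self):
        """A clonotype whose gene is gapped at a masked position adds no count."""
        from tcrforge.io import GermlineGene, GermlineSet

        def make(name, gapped):
            seq = ["A"] * 104
            seq[22], seq[40], seq[103] = "C", "W", "C"
            if gapped:
                seq[72] = "."  # position 73 gapped in this gene only
            return GermlineGene(name=name, chain="alpha", gapped_seq="".join(seq))

        gs = GermlineSet({"TRAV601": make("TRAV601", False), "TRAV602": make("TRAV602", True)})
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV601", "TRAJ3", "CAASGG"),
            Clonotype("d1", "weak", "alpha", "TRAV602", "TRAJ6", "CAASGC"),
        ])
        mask = build_framework_mask(gs, "alpha")
        assert 73 in mask.positions  # occupied in TRAV601, so in the union
        tally = tally_position_aa(lib, gs, mask)["alpha"]
        pi = tally.positions.index(73)
        assert tally.counts[:, :, pi, :20].sum() == 1  # only the ungapped clonotype

    def test_unresolvable_gene_errors(self, reference_germlines):
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV99", "TRAJ3", "CAASGG"),
        ])
        mask = build_framework_mask(reference_germlines, "alpha")
        with pytest.raises(KeyError, match="TRAV99"):
            tally_position_aa(lib, reference_germlines, mask)

    def test_abundance_weighting_optional(self, reference_germlines):
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV13-2", "TRAJ3", "CAASGG", abundance=7),
            Clonotype("d1", "weak", "alpha", "TRAV13-2", "TRAJ6", "CAASGC"),
        ])
        mask = build_framework_mask(reference_germlines, "alpha")
        unweighted = tally_position_aa(lib, reference_germlines, mask)["alpha"]
        weighted = tally_position_aa(
            lib, reference_germlines, mask, weight_by_abundance=True
        )["alpha"]
        pos = 96
        assert unweighted.table("d1", pos, "P").a == 1
        assert weighted.table("d1", pos, "P").a == 7


class TestRunEnrichment:
    def test_single_phenotype_rejected(self, reference_germlines):
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV13-2", "TRAJ3", "CAASGG"),
        ])
        with pytest.raises(ValueError):
            run_enrichment(lib, reference_germlines)

    def test_tiny_library_yields_no_discoveries(self, reference_germlines):
        lib = RepertoireLibrary([
            Clonotype("d1", "dominant", "alpha", "TRAV13-2", "TRAJ3", "CAASGG"),
            Clonotype("d1", "weak", "alpha", "TRAV38-2", "TRAJ3", "CAASGC"),
        ])
        results = run_enrichment(lib, reference_germlines, mode="ngs")
        assert results
        assert not any(r.tested for r in results)

    def test_phenotype_swap_flips_directions(self, reference_germlines):
        cfg = SyntheticConfig(
            n_donors=2,
            n_clonotypes_per_phenotype=300,
            planted_effects=[PlantedEffect("alpha", 96, "L", 4.0)],
            seed=6,
        )
        lib = generate_library(cfg)
        flipped = RepertoireLibrary([
            Clonotype(
                c.donor_id,
                "weak" if c.phenotype == "dominant" else "dominant",
                c.chain, c.v_gene, c.j_gene, c.cdr3_aa, c.abundance,
                c.framework_overrides,
            )
            for c in lib.clonotypes
        ])
        res = {(r.chain, r.position, r.amino_acid): r
               for r in run_enrichment(lib, reference_germlines, mode="ngs")}
        res_f = {(r.chain, r.position, r.amino_acid): r
                 for r in run_enrichment(flipped, reference_germlines, mode="ngs")}
        assert res.keys() == res_f.keys()
        for key, r in res.items():
            rf = res_f[key]
            assert rf.cmh_p == pytest.approx(r.cmh_p, rel=1e-9)
            if r.direction == "dominant-enriched":
                assert rf.direction == "weak-enriched"
            elif r.direction == "weak-enriched":
                assert rf.direction == "dominant-enriched"

    def test_row_permutation_invariance(self, reference_germlines):
        cfg = SyntheticConfig(n_donors=2, n_clonotypes_per_phenotype=100, seed=8)
        lib = generate_library(cfg)
        shuffled = RepertoireLibrary(list(reversed(lib.clonotypes)))
        as_tuples = lambda rs: [
            (r.chain, r.position, r.amino_acid, r.cmh_p, r.p_adjusted) for r in rs
        ]
        assert as_tuples(run_enrichment(lib, reference_germlines)) == as_tuples(
            run_enrichment(shuffled, reference_germlines)
        )

    def test_sanger_mode_has_no_adjustment(self, reference_germlines):
        lib = _toy_library(40, 10, 10, 40)
        results = run_enrichment(lib, reference_germlines, mode="sanger")
        r96 = next(r for r in results if r.position == 96 and r.amino_acid == "L")
        assert r96.p_adjusted is None
        assert r96.cmh_p is None
        assert r96.pooled_p == pytest.approx(
            fisher_two_sided_bruteforce(40, 10, 10, 40), rel=1e-9
        )
        assert r96.direction == "dominant-enriched"

    def test_bonferroni_discoveries_subset_of_raw(self, reference_germlines):
        cfg = SyntheticConfig(
            n_donors=2,
            n_clonotypes_per_phenotype=500,
            planted_effects=[PlantedEffect("alpha", 96, "L", 5.0)],
            seed=10,
        )
        results = run_enrichment(generate_library(cfg), reference_germlines, mode="ngs")
        for r in results:
            if r.tested and r.p_adjusted is not None:
                assert r.p_adjusted >= r.cmh_p - 1e-15


class TestCompareUsage:
    def _usage_library(self, dom_counts, weak_counts, total=100):
        """Three donors; gene TRAV13-2 at the given per-donor counts."""
        clonos = []
        idx = 0
        for phenotype, counts in (("dominant", dom_counts), ("weak", weak_counts)):
            for d, n_gene in enumerate(counts):
                for k in range(total):
                    gene = "TRAV13-2" if k < n_gene else "TRAV23"
                    clonos.append(
                        Clonotype(f"d{d}", phenotype, "alpha", gene, "TRAJ3",
                                  f"CAAS{_cdr3_suffix(idx)}")
                    )
                    idx += 1
        return RepertoireLibrary(clonos)

    def test_identical_frequencies_give_p_one(self):
        lib = self._usage_library([30, 31, 29], [30, 31, 29])
        result = next(
            r for r in compare_v_usage(lib) if r.gene == "TRAV13-2"
        )
        assert result.t_statistic == 0.0
        assert result.p == 1.0

    def test_textbook_two_sample_t(self):
        """(0.3, 0.31, 0.29) vs (0.1, 0.11, 0.09): pooled-variance t by hand."""
        lib = self._usage_library([30, 31, 29], [10, 11, 9])
        result = next(r for r in compare_v_usage(lib) if r.gene == "TRAV13-2")
        dom, weak = [0.30, 0.31, 0.29], [0.10, 0.11, 0.09]
        s2 = (np.var(dom, ddof=1) + np.var(weak, ddof=1)) / 2
        t_hand = (np.mean(dom) - np.mean(weak)) / math.sqrt(s2 * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert result.t_statistic == pytest.approx(t_hand, rel=1e-9)
        assert result.p == pytest.approx(p_hand, rel=1e-9)

    def test_single_donor_skips_test(self):
        lib = self._usage_library([30], [10])
        result = next(r for r in compare_v_usage(lib) if r.gene == "TRAV13-2")
        assert result.skipped
        assert result.per_donor_freq_dominant == [0.30]
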