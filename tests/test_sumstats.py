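"""Summary-statistic IO, harmonization, LD and instrument selection."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlink.sumstats import (
    HaplotypePanel,
    MonomorphicVariantError,
    SumStatsError,
    find_proxy,
    harmonize,
    ld_d_prime_r2,
    read_sumstats,
    select_instruments,
)

from conftest import make_table, make_variant

HEADER = "SNP\tCHR\tBP\tA1\tA2\tFRQ\tBETA\tSE\tP\n"


def write_sumstats(path, rows):
    path.write_text(HEADER + "".join(rows))
    return path


GOOD_ROWS = [
    "rs1\t1\t1000\tA\tG\t0.3\t0.12\t0.02\t1e-9\n",
    "rs2\t1\t2000\tC\tT\t0.4\t-0.08\t0.015\t8e-8\n",
    "rs3\t2\t3000\tG\tA\t0.1\t0.21\t0.04\t2e-7\n",
]


class TestReadSumstats:
    def test_well_formed_file(self, tmp_path):
        t = read_sumstats(write_sumstats(tmp_path / "s.tsv", GOOD_ROWS))
        assert len(t) == 3
        assert t.get("rs2").beta == pytest.approx(-0.08)
        assert len(t.rejected) == 0

    def test_invalid_rows_rejected_and_reported(self, tmp_path):
        rows = GOOD_ROWS + [
            "rs4\t1\t4000\tA\tG\t0.3\t0.1\t0\t1e-5\n",       # se = 0
            "rs5\t1\t5000\tAT\tG\t0.3\t0.1\t0.02\t1e-5\n",   # indel
            "rs6\t1\t6000\tA\tG\t0.3\t0.1\t0.02\t0\n",       # p = 0
            "rs1\t1\t1000\tA\tG\t0.3\t0.12\t0.02\t1e-9\n",   # duplicate rsid
        ]
        t = read_sumstats(write_sumstats(tmp_path / "s.tsv", rows))
        assert len(t) == 3
        assert set(t.rejected["rsid"]) == {"rs4", "rs5", "rs6", "rs1"}

    def test_lowercase_alleles_uppercased(self, tmp_path):
        t = read_sumstats(write_sumstats(
            tmp_path / "s.tsv", ["rs1\t1\t1000\ta\tg\t0.3\t0.1\t0.02\t1e-9\n"]))
        rec = t.get("rs1")
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("SNP\tCHR\tBP\tA1\tA2\tFRQ\tBETA\tP\nrs1\t1\t1\tA\tG\t.3\t.1\t1e-9\n")
        with pytest.raises(SumStatsError, match="SE"):
            read_sumstats(p)

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "s.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(HEADER + GOOD_ROWS[0])
        assert len(read_sumstats(p)) == 1

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(IOError):
            read_sumstats(tmp_path / "nope.tsv")

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("marker\tchr\tbp\tea\toa\tb\ts\tpval\n"
                     "rs1\t1\t1000\tA\tG\t0.1\t0.02\t1e-9\n")
        t = read_sumstats(p, column_map={"rsid": "marker", "chrom": "chr", "pos": "bp",
                                         "effect_allele": "ea", "other_allele": "oa",
                                         "beta": "b", "se": "s", "pvalue": "pval"})
        assert t.get("rs1").eaf is None


class TestHarmonize:
    def _pair(self, e_alleles, o_alleles, o_beta=0.2, e_eaf=0.3, o_eaf=0.3, w=0.08):
        exp = make_table([make_variant("rs1", *e_alleles, beta=0.1, eaf=e_eaf)])
        out = make_table([make_variant("rs1", *o_alleles, beta=o_beta, eaf=o_eaf)])
        return harmonize(exp, out, palindrome_eaf_window=w)[0]

    def test_same_alleles_kept(self):
        p = self._pair(("A", "G"), ("A", "G"))
        assert (p.action, p.beta_out) == ("kept", 0.2)

    def test_swapped_alleles_negate(self):
        p = self._pair(("A", "G"), ("G", "A"), o_eaf=0.7)
        assert p.action == "swapped"
        assert p.beta_out == pytest.approx(-0.2)
        assert p.eaf_out == pytest.approx(0.3)

    def test_strand_flip_keeps_sign(self):
        p = self._pair(("A", "G"), ("T", "C"))
        assert (p.action, p.beta_out) == ("strand-flipped", 0.2)

    def test_swap_plus_flip(self):
        p = self._pair(("A", "G"), ("C", "T"), o_eaf=0.7)
        assert p.action == "swapped+flipped"
        assert p.beta_out == pytest.approx(-0.2)

    def test_palindrome_near_half_dropped(self):
        p = self._pair(("A", "T"), ("A", "T"), e_eaf=0.50, o_eaf=0.3)
        assert p.action == "dropped-palindromic"

    def test_palindrome_resolved_by_frequency(self):
        kept = self._pair(("A", "T"), ("T", "A"), e_eaf=0.2, o_eaf=0.2)
        assert kept.action == "kept" and kept.beta_out == 0.2
        flipped = self._pair(("C", "G"), ("C", "G"), e_eaf=0.2, o_eaf=0.8)
        assert flipped.action == "swapped+flipped"
        assert flipped.beta_out == pytest.approx(-0.2)

    def test_allele_mismatch_dropped_not_kept(self):
        p = self._pair(("A", "G"), ("A", "C"))
        assert p.dropped and p.reason == "allele-mismatch"

    def test_missing_from_outcome(self):
        exp = make_table([make_variant("rs1"), make_variant("rs2", pos=2000)])
        out = make_table([make_variant("rs1")])
        actions = {p.rsid: p.action for p in harmonize(exp, out)}
        assert actions["rs2"] == "dropped-missing"

    def test_idempotent_on_aligned_pair(self):
        exp = make_table([make_variant("rs1", beta=0.1)])
        out = make_table([make_variant("rs1", beta=0.25)])
        first = harmonize(exp, out)[0]
        realigned = make_table([make_variant("rs1", beta=first.beta_out)])
        second = harmonize(exp, realigned)[0]
        assert second.action == "kept"
        assert second.beta_out == first.beta_out

    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.01, 0.99))
    @settings(max_examples=50, derandomize=True)
    def test_negate_and_swap_round_trip(self, beta, eaf):
        """Representing the outcome on the opposite allele leaves the
        harmonized effect unchanged."""
        exp = make_table([make_variant("rs1", "A", "G", beta=0.1)])
        out1 = make_table([make_variant("rs1", "A", "G", beta=beta, eaf=eaf)])
        out2 = make_table([make_variant("rs1", "G", "A", beta=-beta, eaf=1 - eaf)])
        p1, p2 = harmonize(exp, out1)[0], harmonize(exp, out2)[0]
        assert p1.beta_out == pytest.approx(p2.beta_out)


class TestLD:
    def test_complete_coupling(self, tiny_panel):
        ld = ld_d_prime_r2(tiny_panel, "v1", "v2")
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_independence(self):
        # {AB x4, Ab x4, aB x1, ab x1}: D = 0
        a = np.array([1] * 8 + [0] * 2)
        b = np.array([1] * 4 + [0] * 4 + [1] + [0])
        panel = HaplotypePanel(rsids=["a", "b"], matrix=np.vstack([a, b]))
        ld = ld_d_prime_r2(panel, "a", "b")
        assert ld.d_prime == pytest.approx(0.0)
        assert ld.r2 == pytest.approx(0.0)

    def test_complete_dprime_low_r2(self):
        # {AB x5, aB x3, ab x2}: hand enumeration gives D' = 1, r2 = 0.25 —
        # the signature of a low-frequency allele riding one haplotype
        a = np.array([1] * 5 + [0] * 5)
        b = np.array([1] * 8 + [0] * 2)
        panel = HaplotypePanel(rsids=["a", "b"], matrix=np.vstack([a, b]))
        ld = ld_d_prime_r2(panel, "a", "b")
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(0.25)

    def test_monomorphic_error(self):
        panel = HaplotypePanel(rsids=["a", "b"],
                               matrix=np.array([[1, 1, 1], [1, 0, 1]]))
        with pytest.raises(MonomorphicVariantError):
            ld_d_prime_r2(panel, "a", "b")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, derandomize=True)
    def test_symmetry_and_r2_bound(self, seed):
        """r2 <= D'^2 and symmetry in the variant arguments, random panels."""
        r = np.random.default_rng(seed)
        mat = (r.random((4, 12)) < r.uniform(0.2, 0.8, (4, 1))).astype(int)
        poly = [i for i in range(4) if 0 < mat[i].mean() < 1]
        if len(poly) < 2:
            return
        panel = HaplotypePanel(rsids=[f"v{i}" for i in range(4)], matrix=mat)
        i, j = poly[0], poly[1]
        ld = ld_d_prime_r2(panel, f"v{i}", f"v{j}")
        ld_t = ld_d_prime_r2(panel, f"v{j}", f"v{i}")
        assert ld.r2 == pytest.approx(ld_t.r2)
        assert ld.d_prime == pytest.approx(ld_t.d_prime)
        assert ld.r2 <= ld.d_prime**2 + 1e-9
        assert 0 <= ld.r2 <= 1 and 0 <= ld.d_prime <= 1


class TestFindProxy:
    def _candidates(self):
        return make_table([make_variant("v1", pos=100), make_variant("v2", pos=200),
                           make_variant("v3", pos=300)])

    def test_target_itself_wins(self, tiny_panel):
        assert find_proxy("v1", self._candidates(), tiny_panel) == "v1"

    def test_no_candidate_above_threshold(self, tiny_panel):
        cands = make_table([make_variant("v3", pos=300)])
        assert find_proxy("v1", cands, tiny_panel, r2_min=0.8) is None

    def test_tie_broken_by_distance(self):
        v = np.array([1, 1, 1, 0, 0, 0])
        panel = HaplotypePanel(rsids=["t", "near", "far"],
                               matrix=np.vstack([v, v, v]),
                               pos=np.array([100, 5100, 50100]))
        cands = make_table([make_variant("near", pos=5100),
                            make_variant("far", pos=50100)])
        assert find_proxy("t", cands, panel) == "near"

    def test_missing_target_raises(self, tiny_panel):
        with pytest.raises(KeyError):
            find_proxy("nope", self._candidates(), tiny_panel)


def bh_bruteforce(p, q):
    """O(m^2) Benjamini-Hochberg oracle: largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    keep = np.zeros(m, dtype=bool)
    keep[order[:k_star]] = True
    return keep


class TestSelectInstruments:
    def _table(self, pvals, eafs=None):
        eafs = eafs or [0.3] * len(pvals)
        return make_table([make_variant(f"rs{i}", p=p, eaf=f, pos=1000 * (i + 1))
                           for i, (p, f) in enumerate(zip(pvals, eafs))])

    def test_gws_threshold(self):
        sel = select_instruments(self._table([1e-9, 6e-8]), mode="gws")
        assert sel.rsids == ["rs0"]

    def test_bh_all_selected(self):
        sel = select_instruments(self._table([0.01, 0.02, 0.04]), mode="fdr", fdr_q=0.05)
        assert sel.rsids == ["rs0", "rs1", "rs2"]

    def test_bh_none_selected(self):
        assert select_instruments(self._table([0.5]), mode="fdr").rsids == []

    def test_low_maf_flagged_not_removed(self):
        sel = select_instruments(self._table([1e-9, 1e-9], eafs=[0.3, 0.01]))
        assert sel.rsids == ["rs0", "rs1"]
        assert sel.low_maf == {"rs1"}

    def test_empty_table_warns(self):
        import pandas as pd

        from mrlink.sumstats import SumStatsTable
        empty = SumStatsTable(pd.DataFrame(columns=["rsid", "pvalue"]).set_index(
            "rsid", drop=False))
        with pytest.warns(UserWarning):
            assert select_instruments(empty).rsids == []

    @given(st.integers(0, 2**32 - 1), st.integers(2, 200))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_bh_matches_bruteforce(self, seed, m):
        r = np.random.default_rng(seed)
        p = 10 ** r.uniform(-6, 0, m)
        table = self._table(list(p))
        sel = select_instruments(table, mode="fdr", fdr_q=0.05)
        expect = bh_bruteforce(p, 0.05)
        assert set(sel.rsids) == {f"rs{i}" for i in np.flatnonzero(expect)}

    def test_gws_invariant_to_row_order(self, rng):
        p = 10 ** rng.uniform(-10, 0, 30)
        table = self._table(list(p))
        perm = rng.permutation(30)
        shuffled = make_table([table.get(f"rs{i}") for i in perm])
        a = select_instruments(table, mode="gws").rsids
        b = select_instruments(shuffled, mode="gws").rsids
        assert set(a) == set(b)
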