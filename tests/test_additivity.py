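"""Additivity-deviation scoring against brute-force set algebra."""

import numpy as np
import pandas as pd
import pytest

from ssapkit.additivity import (classify_parental_bands, deviation_summary,
                                parental_origin_of_losses,
                                partition_sharing_categories,
                                score_polyploid_deviation, sharing_categories)
from ssapkit.marker_data import MarkerMatrix, TaxonScheme, taxon_presence

from conftest import matrix_for_scheme


def scored(m, s):
    return score_polyploid_deviation(classify_parental_bands(m, s))


def brute_force_labels(m, s):
    """Independent per-locus enumeration using plain python sets."""
    pres = taxon_presence(m, s)
    out = {}
    for locus in m.locus_ids:
        mat = bool(pres.loc[s.maternal_diploid, locus])
        pat = bool(pres.loc[s.paternal_diploid, locus])
        if mat and pat:
            status = "shared_parental"
        elif mat:
            status = "maternal_specific"
        elif pat:
            status = "paternal_specific"
        else:
            status = "absent_in_parents"
        labels = {}
        for t in s.polyploids:
            present = bool(pres.loc[t, locus])
            if status != "absent_in_parents":
                labels[t] = "additive_present" if present else "missing"
            else:
                labels[t] = "new" if present else "absent_everywhere"
        out[locus] = (status, labels)
    return out


class TestClassification:
    def test_three_locus_example(self, small_scheme):
        # paternal carries {L1,L2}, maternal {L2,L3}
        accs = tuple(small_scheme.taxon_of)
        calls = np.zeros((3, len(accs)), dtype=int)
        for j, a in enumerate(accs):
            t = small_scheme.taxon_of[a]
            calls[0, j] = 1 if t == "TRI" else 0       # L1 paternal only
            calls[1, j] = 1 if t in ("TRI", "SYL") else 0  # L2 shared
            calls[2, j] = 1 if t == "SYL" else 0       # L3 maternal only
        m = MarkerMatrix("TE", ("L1", "L2", "L3"), accs, calls)
        c = classify_parental_bands(m, small_scheme)
        assert c.parental_status["L1"] == "paternal_specific"
        assert c.parental_status["L2"] == "shared_parental"
        assert c.parental_status["L3"] == "maternal_specific"

    def test_reconstructed_parental_row_matches_printed_distribution(self, small_scheme):
        """A matrix with 15 shared / 37 paternal / 35 maternal loci yields the
        printed 87-band parental distribution for the Au family."""
        accs = tuple(small_scheme.taxon_of)
        rows, loci = [], []
        def block(n, in_tri, in_syl, tag):
            for i in range(n):
                loci.append(f"{tag}{i}")
                rows.append([1 if ((small_scheme.taxon_of[a] == "TRI" and in_tri)
                                   or (small_scheme.taxon_of[a] == "SYL" and in_syl))
                             else 0 for a in accs])
        block(15, True, True, "sh")
        block(37, True, False, "pa")
        block(35, False, True, "ma")
        m = MarkerMatrix("Au", tuple(loci), accs, np.array(rows))
        counts = classify_parental_bands(m, small_scheme).parental_counts()
        assert counts == {"total": 87, "shared": 15,
                          "maternal_specific": 35, "paternal_specific": 37}

    def test_counts_match_brute_force_on_random_matrices(self, small_scheme, rng):
        for _ in range(25):
            m = matrix_for_scheme(rng, small_scheme, n_loci=40,
                                  p=rng.uniform(0.1, 0.7))
            c = scored(m, small_scheme)
            bf = brute_force_labels(m, small_scheme)
            for locus in m.locus_ids:
                status, labels = bf[locus]
                assert c.parental_status[locus] == status
                for t in small_scheme.polyploids:
                    assert c.labels.loc[locus, t] == labels[t]


class TestDeviationScoring:
    def test_perfect_additivity(self, small_scheme, rng):
        m = matrix_for_scheme(rng, small_scheme, n_loci=20, p=0.5)
        pres = taxon_presence(m, small_scheme)
        union = (pres.loc["SYL"] | pres.loc["TRI"]).to_numpy()
        # overwrite polyploid accessions with the exact parental union
        calls = m.calls.copy()
        for j, a in enumerate(m.accession_ids):
            if small_scheme.taxon_of[a] in small_scheme.polyploids:
                calls[:, j] = union
        m2 = MarkerMatrix("TE", m.locus_ids, m.accession_ids, calls)
        s = deviation_summary(scored(m2, small_scheme))
        assert s.new.in_all == 0 and s.lost.in_all == 0

    def test_total_loss(self, small_scheme, rng):
        m = matrix_for_scheme(rng, small_scheme, n_loci=20, p=0.6)
        calls = m.calls.copy()
        for j, a in enumerate(m.accession_ids):
            if small_scheme.taxon_of[a] in small_scheme.polyploids:
                calls[:, j] = 0
        m2 = MarkerMatrix("TE", m.locus_ids, m.accession_ids, calls)
        c = scored(m2, small_scheme)
        s = deviation_summary(c)
        assert s.lost.per_taxon["NUD"] == s.parental["total"]
        assert s.new.in_all == 0

    def test_order_invariance(self, small_scheme, rng):
        m = matrix_for_scheme(rng, small_scheme, n_loci=30)
        s1 = deviation_summary(scored(m, small_scheme))
        perm_l = rng.permutation(m.n_loci)
        perm_a = rng.permutation(m.n_accessions)
        m2 = MarkerMatrix(m.te_family,
                          tuple(m.locus_ids[i] for i in perm_l),
                          tuple(m.accession_ids[j] for j in perm_a),
                          m.calls[np.ix_(perm_l, perm_a)])
        s2 = deviation_summary(scored(m2, small_scheme))
        assert s1.new.categories == s2.new.categories
        assert s1.lost.categories == s2.lost.categories
        assert s1.parental == s2.parental


class TestSharingCategories:
    def test_powerset_enumeration_oracle(self, small_scheme, rng):
        for _ in range(20):
            m = matrix_for_scheme(rng, small_scheme, n_loci=40,
                                  p=rng.uniform(0.2, 0.6))
            c = scored(m, small_scheme)
            for block, target in (("new", "new"), ("lost", "missing")):
                got = partition_sharing_categories(c, block)
                want = {cat: 0 for cat in sharing_categories(small_scheme.polyploids)}
                for locus in m.locus_ids:
                    subset = tuple(t for t in small_scheme.polyploids
                                   if c.labels.loc[locus, t] == target)
                    if subset:
                        want["+".join(subset)] += 1
                assert got == want
                assert sum(got.values()) == sum(
                    1 for locus in m.locus_ids
                    if any(c.labels.loc[locus, t] == target
                           for t in small_scheme.polyploids))

    def test_single_polyploid_scheme(self, rng):
        taxon_of = {"s1": "SYL", "s2": "SYL", "t1": "TRI", "t2": "TRI",
                    "p1": "POL", "p2": "POL"}
        s = TaxonScheme(taxon_of, "SYL", "TRI", ("POL",))
        m = matrix_for_scheme(rng, s, n_loci=25, p=0.5)
        c = scored(m, s)
        for block, target in (("new", "new"), ("lost", "missing")):
            got = partition_sharing_categories(c, block)
            assert list(got) == ["POL"]
            assert got["POL"] == int((c.labels["POL"] == target).sum())

    def test_invalid_block_rejected(self, small_scheme, rng):
        c = scored(matrix_for_scheme(rng, small_scheme), small_scheme)
        with pytest.raises(Exception):
            partition_sharing_categories(c, "gained")


class TestLossOrigin:
    def _matrix_with_losses(self, scheme, n_pat, n_mat, lose_pat, lose_mat):
        accs = tuple(scheme.taxon_of)
        rows, loci = [], []
        for i in range(n_pat):
            lost = i < lose_pat
            loci.append(f"p{i}")
            rows.append([1 if (scheme.taxon_of[a] == "TRI"
                               or (not lost and scheme.taxon_of[a] in scheme.polyploids))
                         else 0 for a in accs])
        for i in range(n_mat):
            lost = i < lose_mat
            loci.append(f"m{i}")
            rows.append([1 if (scheme.taxon_of[a] == "SYL"
                               or (not lost and scheme.taxon_of[a] in scheme.polyploids))
                         else 0 for a in accs])
        return MarkerMatrix("TE", tuple(loci), accs, np.array(rows))

    def test_all_paternal_losses(self, small_scheme):
        m = self._matrix_with_losses(small_scheme, 10, 10, 4, 0)
        lo = parental_origin_of_losses(scored(m, small_scheme), "NUD")
        assert lo.paternal_lost == 4 and lo.maternal_lost == 0
        assert lo.fraction_paternal == 1.0

    def test_balanced_losses(self, small_scheme):
        m = self._matrix_with_losses(small_scheme, 15, 15, 10, 10)
        lo = parental_origin_of_losses(scored(m, small_scheme), "REP")
        assert (lo.paternal_lost, lo.maternal_lost) == (10, 10)
        assert lo.fraction_paternal == 0.5

    def test_no_attributable_losses_flagged(self, small_scheme):
        m = self._matrix_with_losses(small_scheme, 5, 5, 0, 0)
        lo = parental_origin_of_losses(scored(m, small_scheme), "NUD")
        assert lo.fraction_paternal is None and lo.attributable == 0


class TestSummaryPercentConventions:
    def _au_like(self, scheme):
        """87 parental bands, 21 new in >=1 polyploid (17 in NUD), NUD misses 49."""
        accs = tuple(scheme.taxon_of)
        rows, loci = [], []
        def add(tag, n, tri, syl, nud, rep, isl):
            flags = {"TRI": tri, "SYL": syl, "NUD": nud, "REP": rep, "ISL": isl}
            for i in range(n):
                loci.append(f"{tag}{i}")
                rows.append([1 if flags[scheme.taxon_of[a]] else 0 for a in accs])
        add("keep", 38, True, True, True, True, True)      # additive everywhere
        add("lostN", 49, True, False, False, True, True)   # missing in NUD only
        add("newN", 17, False, False, True, False, False)  # new in NUD only
        add("newO", 4, False, False, False, True, True)    # new elsewhere
        return MarkerMatrix("Au", tuple(loci), accs, np.array(rows))

    def test_new_and_lost_percentages(self, small_scheme):
        s = deviation_summary(scored(self._au_like(small_scheme), small_scheme))
        assert s.parental["total"] == 87
        assert s.new.in_all == 21
        assert s.new.in_all_pct() == pytest.approx(100 * 21 / 87)   # 24.1
        assert s.new.per_taxon["NUD"] == 17
        assert s.new.per_taxon_pct("NUD") == pytest.approx(100 * 17 / 21)  # 81
        assert s.lost.per_taxon["NUD"] == 49
        assert s.lost.per_taxon_pct("NUD") == pytest.approx(100 * 49 / 87)  # 56.3
        assert round(s.new.in_all_pct(), 1) == 24.1
        assert round(s.lost.per_taxon_pct("NUD"), 1) == 56.3
        assert round(s.new.per_taxon_pct("NUD")) == 81

    def test_block_invariants(self, small_scheme, rng):
        m = matrix_for_scheme(rng, small_scheme, n_loci=50, p=0.4)
        s = deviation_summary(scored(m, small_scheme))
        for blk in (s.new, s.lost):
            assert sum(blk.categories.values()) == blk.in_all
            for t in small_scheme.polyploids:
                assert blk.per_taxon[t] == sum(
                    v for c, v in blk.categories.items() if t in c.split("+"))
        assert s.lost.in_all <= s.parental["total"]
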