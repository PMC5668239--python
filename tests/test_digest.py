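"""Digest engine: cut-site location, fragment sets, oracle equivalence."""

from itertools import product

import numpy as np
import pytest
from Bio import Restriction
from Bio.Seq import Seq

from entorflp.digest import (
    DEFAULT_CATALOG,
    FragmentSet,
    RestrictionEnzyme,
    digest,
    find_cut_sites,
    load_catalog,
    parse_catalog,
)
from entorflp.iupac import NucleotideSequence, ValidationError, reverse_complement

ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_cut_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Expansion-search oracle: enumerate concrete words, string-search both
    strands, map footprints to top-strand cut coordinates."""
    motif = enzyme.recognition.motif
    m = len(motif)
    words = {"".join(w) for w in product(*(ORACLE_SETS[s] for s in motif))}
    rc_words = {
        "".join({"A": "T", "T": "A", "C": "G", "G": "C"}[c] for c in w[::-1])
        for w in words
    }
    cuts = set()
    for word in words:
        start = seq.find(word)
        while start != -1:
            cuts.add(start + enzyme.cut_top)
            start = seq.find(word, start + 1)
    for word in rc_words:
        start = seq.find(word)
        while start != -1:
            cuts.add(start + m - enzyme.cut_bottom)
            start = seq.find(word, start + 1)
    return sorted(c for c in cuts if 0 < c < len(seq))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCatalog:
    def test_default_catalog_is_the_published_four(self):
        assert set(DEFAULT_CATALOG) == {"MslI", "DdeI", "HincII", "HaeIII"}
        msl = DEFAULT_CATALOG["MslI"]
        assert (msl.recognition.motif, msl.cut_top, msl.cut_bottom) == ("CAYNNNNRTG", 5, 5)
        assert DEFAULT_CATALOG["DdeI"].cut_top == 1
        assert not DEFAULT_CATALOG["DdeI"].is_blunt
        assert DEFAULT_CATALOG["HincII"].is_blunt

    def test_round_trip_through_file(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("EcoRI\tGAATTC\t1\t5\n")
        cat = load_catalog(p)
        assert cat["EcoRI"].recognition.motif == "GAATTC"

    def test_malformed_line_rejected(self):
        with pytest.raises(ValidationError, match="line 1"):
            parse_catalog("EcoRI GAATTC 1 5\n")


class TestFindCutSites:
    def test_mslI_blunt_cut_in_site_middle(self):
        assert find_cut_sites("AAAAACATTGGTATGAAAAA", DEFAULT_CATALOG["MslI"]) == [10]

    def test_ddeI_cut_offset(self):
        assert find_cut_sites("GGCTTAGGG", DEFAULT_CATALOG["DdeI"]) == [3]

    def test_no_site_no_cuts(self):
        assert find_cut_sites("ATATATATAT", DEFAULT_CATALOG["HaeIII"]) == []

    def test_agrees_with_biopython_restriction(self):
        """Independent library cross-check on random concrete sequences.

        Bio.Restriction reports the 1-based first base after the cut, i.e.
        our 0-based cut coordinate + 1.
        """
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(50, 800)))
            for name, enzyme in DEFAULT_CATALOG.items():
                ours = find_cut_sites(s, enzyme)
                theirs = sorted(
                    p - 1 for p in getattr(Restriction, name).search(Seq(s))
                )
                theirs = [c for c in theirs if 0 < c < len(s)]
                assert ours == theirs, (name, s)


class TestDigest:
    def test_no_sites_single_full_length_fragment(self):
        fs = digest("ATATATATAT", [DEFAULT_CATALOG["HaeIII"]])
        assert fs.fragment_lengths == [10]

    def test_two_planted_sites_partition(self):
        rng = np.random.default_rng(3)
        # HincII cut at 300 (site at 297), HaeIII cut at 700 (site at 698)
        s = list(random_seq(rng, 1000))
        s[297:303] = "GTTAAC"
        s[698:702] = "GGCC"
        s = "".join(s)
        fs = digest(s, [DEFAULT_CATALOG["HincII"], DEFAULT_CATALOG["HaeIII"]])
        planted = {300, 700}
        assert planted <= set(fs.cut_positions)
        assert sum(fs.fragment_lengths) == 1000
        if set(fs.cut_positions) == planted:  # no chance sites in background
            assert fs.fragment_lengths == [400, 300, 300]

    def test_empty_enzyme_list_rejected(self):
        with pytest.raises(ValidationError):
            digest("ACGT", [])

    def test_conservation_union_and_oracle_on_random_sequences(self):
        """1,000 seeded random sequences: lengths sum to input length, the
        double-digest cut set is the union of singles, and cut sets equal the
        expansion-search oracle."""
        rng = np.random.default_rng(20171102)
        enzymes = list(DEFAULT_CATALOG.values())
        for _ in range(1000):
            s = random_seq(rng, int(rng.integers(200, 400)))
            all_cuts = set()
            for enz in enzymes:
                fs = digest(s, [enz])
                assert sum(fs.fragment_lengths) == len(s)
                assert len(fs) == len(fs.cut_positions) + 1
                assert set(fs.cut_positions) == set(oracle_cut_sites(s, enz))
                all_cuts |= set(fs.cut_positions)
            combined = digest(s, enzymes)
            assert set(combined.cut_positions) == all_cuts
            assert sum(combined.fragment_lengths) == len(s)

    def test_reverse_complement_preserves_fragment_multiset(self):
        """Fragment lengths are strand-symmetric.

        Exactly so for blunt cutters.  For sticky-end enzymes the top-strand
        cut convention makes the two *terminal* fragments each shift by the
        overhang length when the molecule is read from the other strand;
        internal fragments are invariant.
        """
        rng = np.random.default_rng(8)
        for _ in range(50):
            s = random_seq(rng, 500)
            for enz in DEFAULT_CATALOG.values():
                a = digest(s, [enz]).fragment_lengths
                b = digest(reverse_complement(s), [enz]).fragment_lengths
                if enz.is_blunt:
                    assert sorted(a) == sorted(b)
                else:
                    assert len(a) == len(b) and sum(a) == sum(b)
                    assert all(
                        abs(x - y) <= enz.overhang
                        for x, y in zip(sorted(a), sorted(b))
                    )

    def test_non_palindromic_user_enzyme_both_strands(self):
        # BspQI-like: GCTCTTC N1 (non-palindromic)
        enz = RestrictionEnzyme("BspQIlike", "GCTCTTC", 7, 7)
        s = "AAGCTCTTCAAAAAAA" + reverse_complement("GCTCTTC") + "AAAA"
        cuts = find_cut_sites(s, enz)
        # + site at 2 cuts at 9; - site at 16 cuts at 16+7-7=16
        assert cuts == [9, 16]


class TestReferenceBandSizes:
    """Digestion of the synthetic reference amplicons echoes the published
    band structure of the four species."""

    def _lengths(self, groups, label, enzymes):
        (grp,) = [g for g in groups if g.label == label]
        return digest(grp.members[0], [DEFAULT_CATALOG[e] for e in enzymes]).fragment_lengths

    def test_ddeI_edible_pattern(self, full_amplicons):
        lengths = self._lengths(full_amplicons, "E. sarcopum-like", ["DdeI"])
        assert [x for x in lengths if x >= 150] == [366, 296, 250]

    def test_ddeI_lacus_major_band(self, full_amplicons):
        lengths = self._lengths(full_amplicons, "E. lacus-like", ["DdeI"])
        assert [x for x in lengths if x >= 150] == [690]
        assert all(65 <= x <= 146 for x in lengths if x < 150)

    def test_hincII_haeIII_major_bands(self, full_amplicons):
        for label, expected in [
            ("E. sarcopum-like", 802),
            ("E. lacus-like", 645),
            ("E. subrhodopolium-like", 645),
            ("E. pseudorhodopolium-like", 502),
        ]:
            lengths = self._lengths(full_amplicons, label, ["HincII", "HaeIII"])
            assert max(lengths) == expected

    def test_mslI_cuts_only_the_edible_group(self, full_amplicons):
        for g in full_amplicons:
            frags = digest(g.members[0], [DEFAULT_CATALOG["MslI"]]).fragment_lengths
            if g.label == "E. sarcopum-like":
                assert len(frags) == 3 and 80 in frags
            else:
                assert frags == [1075]
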