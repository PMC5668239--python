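"""Panel selection, decision-key compilation, classification, mixtures."""

import logging

import pytest

from entorflp.assay import (
    UNDETERMINED,
    CoverageError,
    EnzymeTreatment,
    GelParams,
    SpeciesGroup,
    build_key,
    classify,
    default_treatments,
    detect_contaminant,
    select_panel,
    treatment_separates,
)
from entorflp.iupac import NucleotideSequence, ValidationError
from entorflp.synthetic import FixtureSpec, Feature, GroupSpec, make_mixture, make_species_groups

MSL = EnzymeTreatment(("MslI",))
DDE = EnzymeTreatment(("DdeI",))
HH = EnzymeTreatment(("HincII", "HaeIII"))


@pytest.fixture(scope="module")
def snp_groups():
    """Three groups separated only by the MslI-site polymorphism."""
    # every group has a distinct MslI profile: edible cuts at 185, poison-A
    # at 85 (its site sits elsewhere), poison-B not at all
    spec = FixtureSpec(
        seed=11,
        template_length=400,
        features=(
            Feature("msl1", 180, "CATTGGTATG"),
            Feature("msl2", 80, "CTTTGGTATG"),
        ),
        groups=(
            GroupSpec("edible-like", "edible", {}, n_members=2),
            GroupSpec(
                "poison-A",
                "poisonous",
                {"msl1": "CTTTGGTATG", "msl2": "CATTGGTATG"},
                n_members=2,
            ),
            GroupSpec("poison-B", "poisonous", {"msl1": "CTCTGATATG"}, n_members=2),
        ),
    )
    return make_species_groups(spec)


class TestTreatmentSeparates:
    def test_mslI_separates_edible_from_each_poisonous_clade(self, full_amplicons):
        edible = full_amplicons[0]
        for poisonous in full_amplicons[1:]:
            assert treatment_separates(MSL, edible, poisonous)

    def test_ddeI_fails_on_clades_II_and_III(self, full_amplicons):
        sub = next(g for g in full_amplicons if "subrhodopolium" in g.label)
        pse = next(g for g in full_amplicons if "pseudorhodopolium" in g.label)
        assert not treatment_separates(DDE, sub, pse)
        assert treatment_separates(HH, sub, pse)

    def test_group_vs_itself(self, full_amplicons):
        g = full_amplicons[0]
        assert not treatment_separates(MSL, g, g)

    def test_inconsistent_group_logs_discordant_member(self, caplog):
        # second member has an extra DdeI site -> wildly different pattern
        a = NucleotideSequence(id="m1", residues="A" * 300)
        b = NucleotideSequence(id="m2", residues="A" * 150 + "CTAAG" + "A" * 145)
        g1 = SpeciesGroup("mixed", (a, b))
        g2 = SpeciesGroup("other", (NucleotideSequence(id="o", residues="G" * 300),))
        with caplog.at_level(logging.WARNING):
            assert not treatment_separates(DDE, g1, g2)
        assert "m2" in caplog.text


class TestSelectPanel:
    def test_reference_panel_fully_covered(self, full_amplicons):
        panel = select_panel(default_treatments(), full_amplicons)
        key = build_key(panel, full_amplicons)  # raises if any pair uncovered
        assert 1 <= len(panel) <= 3
        assert set(key.labels) == {g.label for g in full_amplicons}

    def test_deterministic(self, full_amplicons):
        p1 = select_panel(default_treatments(), full_amplicons)
        p2 = select_panel(default_treatments(), full_amplicons)
        assert [t.name for t in p1] == [t.name for t in p2]

    def test_single_discriminating_enzyme_gives_panel_of_one(self, snp_groups):
        panel = select_panel(default_treatments(), snp_groups)
        assert [t.name for t in panel] == ["MslI"]

    def test_planted_snp_enzyme_always_selected(self, snp_groups):
        # the only polymorphism sits inside the MslI site, so MslI must appear
        panel = select_panel(default_treatments(), snp_groups)
        assert any("MslI" in t.enzymes for t in panel)

    def test_fewer_than_two_groups_rejected(self, full_amplicons):
        with pytest.raises(ValidationError):
            select_panel(default_treatments(), full_amplicons[:1])

    def test_uncoverable_pair_raises_with_partial_cover(self, snp_groups):
        # restrict candidates to DdeI, which sees no polymorphism at all
        with pytest.raises(CoverageError) as err:
            select_panel([DDE], snp_groups)
        assert err.value.uncovered_pairs  # names the unseparated pairs


class TestKeyAndClassify:
    def test_published_order_key_is_self_consistent(self, full_amplicons):
        key = build_key(default_treatments(), full_amplicons)
        for g in full_amplicons:
            for m in g.members:
                assert classify(m, key) == g.label

    def test_minimal_panel_key_is_self_consistent(self, full_amplicons):
        panel = select_panel(default_treatments(), full_amplicons)
        key = build_key(panel, full_amplicons)
        for g in full_amplicons:
            for m in g.members:
                assert classify(m, key) == g.label

    def test_two_group_key_from_synthetic_snp(self, snp_groups):
        key = build_key([MSL], snp_groups[:2])
        assert len(key.treatments) == 1
        for g in snp_groups[:2]:
            assert classify(g.members[0], key) == g.label

    def test_observed_intact_short_band_routes_to_poisonous(self, short_amplicons):
        edible = short_amplicons[0]
        pooled = SpeciesGroup(
            "poisonous clade (not E. sarcopum)",
            sum((g.members for g in short_amplicons[1:]), ()),
            "poisonous",
        )
        key = build_key([MSL], [edible, pooled])
        assert classify({"MslI": [214]}, key) == "poisonous clade (not E. sarcopum)"
        assert classify(edible.members[0], key) == edible.label

    def test_missing_observation_names_treatment(self, full_amplicons):
        key = build_key(default_treatments(), full_amplicons)
        with pytest.raises(ValidationError, match="MslI"):
            classify({}, key)

    def test_unseen_pattern_is_undetermined(self, full_amplicons):
        key = build_key(default_treatments(), full_amplicons)
        observed = {"MslI": [3000], "DdeI": [3000], "HincII+HaeIII": [3000]}
        assert classify(observed, key) == UNDETERMINED

    def test_uncovered_pair_fails_key_build(self, snp_groups):
        with pytest.raises(CoverageError):
            build_key([DDE], snp_groups)


class TestDetectContaminant:
    def test_trace_poisonous_in_edible_pool(self, short_amplicons):
        edible, poisonous = short_amplicons[0], short_amplicons[2]
        pool = make_mixture([edible, poisonous], [6, 1], seed=3)
        assert detect_contaminant(pool, MSL, 214)

    def test_edible_only_pool_is_negative(self, short_amplicons):
        pool = make_mixture([short_amplicons[0]], [1], seed=3)
        assert not detect_contaminant(pool, MSL, 214)

    def test_monotone_in_pool_membership(self, short_amplicons):
        edible, poisonous = short_amplicons[0], short_amplicons[1]
        pool = list(make_mixture([edible], [1], seed=5))
        assert not detect_contaminant(pool, MSL, 214)
        for extra in poisonous.members:
            pool.append(extra)
            assert detect_contaminant(pool, MSL, 214)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            detect_contaminant([], MSL, 214)
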