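"""Synthetic templates, species groups and mixtures with planted features.

Real reference material for the *Entoloma* assay lives in public sequence
archives; this module generates stand-ins so that every pipeline stage is
testable and reproducible from a seed alone.  Backgrounds are sampled
uniformly over A/C/G/T under *motif avoidance*: no recognition site of the
four catalog enzymes ever arises by chance, so the only cut sites in a
template are the ones planted.  All templates here are synthetic constructs,
not deposited sequences.

Two ready-made fixture sets are provided:

* :func:`make_reference_panel` — four species groups emulating the published
  assay geometry: a 1,075-bp full ITS-like amplicon and a 214-bp short
  amplicon; the edible-like group carries the cuttable MslI decamer
  ``CATTGGTATG`` while the three poisonous-like groups carry single-base
  variants of ``CTYTGRTATG`` that break the degenerate match; DdeI and
  HincII/HaeIII sites are placed so the major virtual bands echo the
  published sizes (366/296/250, 690, and 502/645/802 bp).  Members within a
  group differ by a 9-nt or 1-nt indel, mimicking observed intra-species
  length polymorphism.
* :func:`make_divergent_groups` — two groups on a common 926-column
  alignment separated by a fixed number of substitutions, for p-distance
  work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay import SpeciesGroup
from .digest import DEFAULT_CATALOG, RestrictionEnzyme
from .iupac import (
    DegeneratePattern,
    NucleotideSequence,
    ValidationError,
    find_matches,
    matches,
    reverse_complement,
)
from .pcr import PRESETS

__all__ = [
    "Feature",
    "GroupSpec",
    "FixtureSpec",
    "DEFAULT_SEED",
    "make_template",
    "make_species_groups",
    "make_reference_panel",
    "make_mixture",
    "make_divergent_groups",
]

#: Default seed for the shipped fixture suite.
DEFAULT_SEED = 20171102

_BASES = "ACGT"


@dataclass(frozen=True)
class Feature:
    """A fixed word planted at an absolute template position."""

    name: str
    start: int
    word: str
    kind: str = "enzyme-site"  # primer-fwd | primer-rev | enzyme-site | other

    @property
    def end(self) -> int:
        return self.start + len(self.word)


@dataclass(frozen=True)
class GroupSpec:
    """Per-group overrides of planted feature words."""

    label: str
    status: str = "unknown"
    substitutions: Mapping[str, str] = field(default_factory=dict)
    n_members: int = 1


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to grow a reproducible set of species groups."""

    seed: int = DEFAULT_SEED
    template_length: int = 1135
    features: tuple[Feature, ...] = ()
    groups: tuple[GroupSpec, ...] = ()
    indel_jitter: int = 0
    #: indels are only placed in background strictly inside this window
    jitter_window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: f.start))
        object.__setattr__(self, "features", feats)
        for a, b in zip(feats, feats[1:]):
            if a.end > b.start:
                raise ValidationError(f"features {a.name} and {b.name} overlap")
        if feats and (feats[0].start < 0 or feats[-1].end > self.template_length):
            raise ValidationError("feature outside template bounds")


def _avoidance_motifs(catalog: Mapping[str, RestrictionEnzyme]) -> list[DegeneratePattern]:
    """Both-strand recognition motifs the background must never contain."""
    out: list[DegeneratePattern] = []
    for enz in catalog.values():
        out.append(enz.recognition)
        rc = enz.recognition.reverse_complement()
        if rc.motif != enz.recognition.motif:
            out.append(rc)
    return out


def _safe_base(prefix: list[str], rng: np.random.Generator, motifs) -> str:
    """A uniform random base that completes no forbidden motif at this position."""
    order = rng.permutation(4)
    for j in order:
        b = _BASES[j]
        ok = True
        for m in motifs:
            k = len(m)
            if len(prefix) >= k - 1:
                window = "".join(prefix[len(prefix) - k + 1 :]) + b
                if matches(m, window):
                    ok = False
                    break
        if ok:
            return b
    raise RuntimeError("no safe base exists (motif set too dense)")  # pragma: no cover


def _assemble(length, features, rng, motifs) -> str:
    fixed: dict[int, str] = {}
    for f in features:
        for i, ch in enumerate(f.word):
            fixed[f.start + i] = ch
    out: list[str] = []
    for i in range(length):
        if i in fixed:
            out.append(fixed[i])
        else:
            out.append(_safe_base(out, rng, motifs))
    return "".join(out)


def _expected_footprints(features, motif) -> set[int]:
    exp: set[int] = set()
    for f in features:
        for s, _ in find_matches(motif, f.word, both_strands=True):
            exp.add(f.start + s)
    return exp


def _verify(template: str, features, catalog) -> bool:
    """Only planted sites exist: motif footprints match the plan exactly."""
    for enz in catalog.values():
        found = {s for s, _ in find_matches(enz.recognition, template, both_strands=True)}
        if found != _expected_footprints(features, enz.recognition):
            return False
    return True


def make_template(
    length: int,
    features: Sequence[Feature],
    rng: np.random.Generator,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    max_tries: int = 500,
) -> str:
    """Assemble a template with exactly the planted enzyme sites.

    Background bases are chosen online so they never complete a forbidden
    motif; a motif can still arise across a background/feature junction, in
    which case the whole template is resampled (verification is exact).
    """
    motifs = _avoidance_motifs(catalog)
    for _ in range(max_tries):
        template = _assemble(length, features, rng, motifs)
        if _verify(template, features, catalog):
            return template
    raise RuntimeError(f"could not assemble a clean template in {max_tries} tries")


def _background_runs(spec: FixtureSpec) -> list[tuple[int, int]]:
    """Background intervals between consecutive features."""
    runs = []
    pos = 0
    for f in spec.features:
        if f.start > pos:
            runs.append((pos, f.start))
        pos = f.end
    if pos < spec.template_length:
        runs.append((pos, spec.template_length))
    return runs


def _apply_indel(
    template: str,
    spec: FixtureSpec,
    delta: int,
    rng: np.random.Generator,
    catalog: Mapping[str, RestrictionEnzyme],
    max_tries: int = 200,
) -> tuple[str, list[Feature]]:
    """Insert (delta>0) or delete (delta<0) background inside the jitter window.

    Returns the edited template plus the feature list with shifted
    coordinates, re-verified so no new enzyme site appears.
    """
    lo, hi = spec.jitter_window
    margin = max(len(e.recognition.motif) for e in catalog.values())
    eligible = [
        (max(a, lo) + margin, min(b, hi) - margin)
        for a, b in _background_runs(spec)
        if min(b, hi) - max(a, lo) >= abs(delta) + 2 * margin
    ]
    if not eligible:
        raise ValidationError("no background run can absorb the requested indel")
    motifs = _avoidance_motifs(catalog)
    for _ in range(max_tries):
        a, b = eligible[rng.integers(len(eligible))]
        pos = int(rng.integers(a, b - max(0, -delta) + 1))
        if delta > 0:
            prefix = list(template[:pos])
            insert = []
            for _ in range(delta):
                insert.append(_safe_base(prefix + insert, rng, motifs))
            edited = template[:pos] + "".join(insert) + template[pos:]
        else:
            edited = template[:pos] + template[pos - delta :]
        shifted = [
            Feature(f.name, f.start + delta if f.start >= pos else f.start, f.word, f.kind)
            for f in spec.features
        ]
        if _verify(edited, shifted, catalog):
            return edited, shifted
    raise RuntimeError("could not place indel without creating a new site")


def _group_features(spec: FixtureSpec, group: GroupSpec) -> list[Feature]:
    by_name = {f.name: f for f in spec.features}
    for name, word in group.substitutions.items():
        if name not in by_name:
            raise ValidationError(f"group {group.label}: unknown feature {name!r}")
        old = by_name[name]
        if len(word) != len(old.word):
            raise ValidationError(
                f"group {group.label}: substitution for {name!r} changes feature length"
            )
        by_name[name] = Feature(old.name, old.start, word.upper(), old.kind)
    return [by_name[f.name] for f in spec.features]



def _seq_id(label: str, k: int) -> str:
    """FASTA-safe member id derived from a group label."""
    import re as _re
    return _re.sub(r"[^A-Za-z0-9_-]+", "_", label).strip("_") + f"_syn{k}"

def make_species_groups(
    spec: FixtureSpec,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
) -> list[SpeciesGroup]:
    """Grow the species groups described by *spec*; fully seed-reproducible.

    Member 1 of each group is the canonical template; with ``indel_jitter``
    enabled, member 2 carries a +``indel_jitter`` insertion and member 3 a
    1-nt deletion, both confined to background inside the jitter window.
    """
    rng = np.random.default_rng(spec.seed)
    groups: list[SpeciesGroup] = []
    for g in spec.groups:
        features = _group_features(spec, g)
        gspec = FixtureSpec(
            seed=spec.seed,
            template_length=spec.template_length,
            features=tuple(features),
            groups=(),
            indel_jitter=spec.indel_jitter,
            jitter_window=spec.jitter_window,
        )
        canonical = make_template(spec.template_length, features, rng, catalog)
        members = [NucleotideSequence(id=_seq_id(g.label, 1), residues=canonical)]
        deltas = []
        if g.n_members >= 2 and spec.indel_jitter > 0:
            deltas = [spec.indel_jitter, -1][: g.n_members - 1]
        elif g.n_members >= 2:
            deltas = [0] * (g.n_members - 1)
        for k, delta in enumerate(deltas, start=2):
            if delta == 0:
                edited = canonical
            else:
                edited, _ = _apply_indel(canonical, gspec, delta, rng, catalog)
            members.append(NucleotideSequence(id=_seq_id(g.label, k), residues=edited))
        groups.append(SpeciesGroup(label=g.label, members=tuple(members), status=g.status))
    return groups


# --------------------------------------------------------------------------
# The shipped Entoloma-like reference panel

_FLANK = 30  # template bases outside the full amplicon on each side

_ITS1F = PRESETS["ITS-full"][0].residues
_ITS4 = PRESETS["ITS-full"][1].residues
_SHORTF = PRESETS["ITS2-short"][0].residues
_SHORTR = PRESETS["ITS2-short"][1].residues

#: MslI decamer variants (Fig-style polymorphism): the edible-like group is
#: cuttable, the poisonous-like groups differ at position 2 (A→T) and vary
#: within the degenerate CTYTGRTATG consensus.
MSL_DECAMERS = {
    "E. sarcopum-like": "CATTGGTATG",
    "E. lacus-like": "CTTTGGTATG",
    "E. subrhodopolium-like": "CTCTGATATG",
    "E. pseudorhodopolium-like": "CTTTGATATG",
}


def _amp(pos: int) -> int:
    return _FLANK + pos


def _panel_features() -> dict[str, list[Feature]]:
    """Planted features per species, in full-amplicon coordinates + flank.

    Positions are chosen so complete digestion of the 1,075-bp amplicon
    reproduces the published band structure of each species.
    """
    common = [
        Feature("its1f_fp", _amp(0), _ITS1F, "primer-fwd"),
        Feature("its4_fp", _amp(1055), reverse_complement(_ITS4), "primer-rev"),
        Feature("shortf_fp", _amp(790), _SHORTF, "primer-fwd"),
        Feature("shortr_fp", _amp(988), reverse_complement(_SHORTR), "primer-rev"),
    ]

    def dde(start: int) -> Feature:
        return Feature(f"dde_{start}", _amp(start), "CTAAG")

    def hae(start: int) -> Feature:
        return Feature(f"hae_{start}", _amp(start), "GGCC")

    per_species = {
        "E. sarcopum-like": [
            Feature("msl_site", _amp(860), MSL_DECAMERS["E. sarcopum-like"]),
            Feature("msl_site2", _amp(780), MSL_DECAMERS["E. sarcopum-like"]),
            hae(190),
            dde(295), dde(370), dde(620), dde(708),
        ],
        "E. lacus-like": [
            Feature("msl_site", _amp(860), MSL_DECAMERS["E. lacus-like"]),
            hae(347),
            dde(145), dde(835), dde(933), dde(1009),
        ],
        "E. subrhodopolium-like": [
            Feature("msl_site", _amp(860), MSL_DECAMERS["E. subrhodopolium-like"]),
            hae(347),
            dde(379), dde(519), dde(949),
        ],
        "E. pseudorhodopolium-like": [
            Feature("msl_site", _amp(860), MSL_DECAMERS["E. pseudorhodopolium-like"]),
            hae(348),
            Feature("hinc_489", _amp(489), "GTCGAC"),
            dde(379), dde(519), dde(949),
        ],
    }
    return {label: common + feats for label, feats in per_species.items()}


# Indel-jitter windows (template coordinates) lie inside a large restriction
# fragment of every treatment for that species, so length polymorphism shifts
# major bands by a few bp instead of moving a small fragment across the
# weak-band threshold.
_PANEL_JITTER_WINDOWS = {
    "E. sarcopum-like": (_amp(380), _amp(615)),
    "E. lacus-like": (_amp(360), _amp(770)),
    "E. subrhodopolium-like": (_amp(530), _amp(770)),
    "E. pseudorhodopolium-like": (_amp(530), _amp(770)),
}

_PANEL_STATUS = {
    "E. sarcopum-like": "edible",
    "E. lacus-like": "poisonous",
    "E. subrhodopolium-like": "poisonous",
    "E. pseudorhodopolium-like": "poisonous",
}


def make_reference_panel(
    seed: int = DEFAULT_SEED,
    n_members: int = 3,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
) -> list[SpeciesGroup]:
    """The shipped four-group synthetic reference panel (see module docs)."""
    rng = np.random.default_rng(seed)
    groups: list[SpeciesGroup] = []
    for label, features in _panel_features().items():
        spec = FixtureSpec(
            seed=seed,
            template_length=1075 + 2 * _FLANK,
            features=tuple(features),
            indel_jitter=9,
            # also keeps indels out of the short-amplicon region, so the
            # 214-bp product is invariant across members
            jitter_window=_PANEL_JITTER_WINDOWS[label],
        )
        canonical = make_template(spec.template_length, spec.features, rng, catalog)
        members = [NucleotideSequence(id=_seq_id(label, 1), residues=canonical)]
        for k, delta in enumerate([9, -1][: max(0, n_members - 1)], start=2):
            edited, _ = _apply_indel(canonical, spec, delta, rng, catalog)
            members.append(NucleotideSequence(id=_seq_id(label, k), residues=edited))
        groups.append(
            SpeciesGroup(label=label, members=tuple(members), status=_PANEL_STATUS[label])
        )
    return groups


def make_mixture(
    groups: Sequence[SpeciesGroup],
    proportions: Sequence[float],
    seed: int = DEFAULT_SEED,
    n_total: int = 7,
) -> list[NucleotideSequence]:
    """A seeded multiset of member sequences pooled across groups.

    Every group with positive proportion contributes at least one member;
    the remaining draws follow the normalised proportions.  Emulates a
    quasi-mixed food sample (a trace of a poisonous-like species in an
    edible background).
    """
    if len(groups) != len(proportions):
        raise ValidationError("one proportion per group required")
    if any(p < 0 for p in proportions):
        raise ValidationError("proportions must be non-negative")
    active = [(g, p) for g, p in zip(groups, proportions) if p > 0]
    if not active:
        raise ValidationError("at least one proportion must be positive")
    if n_total < len(active):
        raise ValidationError("n_total smaller than the number of active groups")
    rng = np.random.default_rng(seed)
    pool: list[NucleotideSequence] = []
    for g, _ in active:  # guarantee presence
        pool.append(g.members[int(rng.integers(len(g.members)))])
    weights = np.array([p for _, p in active], dtype=float)
    weights /= weights.sum()
    for _ in range(n_total - len(active)):
        g = active[int(rng.choice(len(active), p=weights))][0]
        pool.append(g.members[int(rng.integers(len(g.members)))])
    return pool


def make_divergent_groups(
    seed: int = DEFAULT_SEED,
    length: int = 926,
    between_subs: int = 25,
    private_subs: int = 2,
    n_per_group: int = 3,
) -> tuple[list[NucleotideSequence], list[NucleotideSequence]]:
    """Two aligned groups separated by a controlled number of substitutions.

    Group B's ancestor differs from group A's at ``between_subs`` sites; every
    member additionally carries ``private_subs`` private substitutions.  All
    mutated sites are disjoint, so each cross-group pair differs at exactly
    ``between_subs + 2 * private_subs`` of the ``length`` columns — with the
    defaults, 29/926 ≈ 3.13%, the magnitude of divergence between sister
    *Entoloma* taxa.
    """
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length)
    needed = between_subs + private_subs * 2 * n_per_group
    sites = rng.choice(length, size=needed, replace=False)
    between_sites = sites[:between_subs]

    def mutate(row, positions):
        row = row.copy()
        for p in positions:
            row[p] = (row[p] + rng.integers(1, 4)) % 4
        return row

    anc_b = mutate(anc, between_sites)
    private = iter(sites[between_subs:].reshape(2 * n_per_group, private_subs))
    to_str = lambda row: "".join(_BASES[i] for i in row)
    group_a = [
        NucleotideSequence(id=f"cladeA_syn{k+1}", residues=to_str(mutate(anc, next(private))))
        for k in range(n_per_group)
    ]
    group_b = [
        NucleotideSequence(id=f"cladeB_syn{k+1}", residues=to_str(mutate(anc_b, next(private))))
        for k in range(n_per_group)
    ]
    return group_a, group_b
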