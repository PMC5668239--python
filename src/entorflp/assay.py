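"""Discriminating-enzyme assay design and sample classification.

This is the analytical heart of the toolkit: given reference species groups
(e.g. edible *E. sarcopum* and the three poisonous *E. rhodopolium*-related
clades *E. lacus*, *E. subrhodopolium*, *E. pseudorhodopolium*), it

1. scores enzyme treatments for their power to separate group pairs on a
   virtual gel (:func:`treatment_separates`),
2. selects a minimal covering panel by greedy set cover
   (:func:`select_panel`),
3. compiles the panel into a deterministic decision key
   (:func:`build_key`), and
4. classifies query samples — sequences, or observed gel band sizes — along
   that key (:func:`classify`), including detection of a poisonous-type
   contaminant in a mixed/cooked sample by persistence of the intact
   undigested amplicon (:func:`detect_contaminant`).

Edibility statuses are metadata labels only; nothing here asserts that a
mushroom is safe to eat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Union

from .digest import DEFAULT_CATALOG, RestrictionEnzyme, digest
from .gel import (
    DEFAULT_RESOLUTION,
    DEFAULT_WEAK_THRESHOLD,
    BandPattern,
    patterns_distinguishable,
    to_band_pattern,
)
from .iupac import NucleotideSequence, ValidationError
from .pcr import Amplicon

logger = logging.getLogger(__name__)

__all__ = [
    "GelParams",
    "SpeciesGroup",
    "EnzymeTreatment",
    "AssayKey",
    "CoverageError",
    "UNDETERMINED",
    "treatment_separates",
    "select_panel",
    "build_key",
    "classify",
    "detect_contaminant",
    "default_treatments",
    "amplify_groups",
    "member_pattern",
]

UNDETERMINED = "undetermined"

SequenceLike = Union[NucleotideSequence, Amplicon]


@dataclass(frozen=True)
class GelParams:
    resolution: float = DEFAULT_RESOLUTION
    weak_threshold: float = DEFAULT_WEAK_THRESHOLD


@dataclass(frozen=True)
class SpeciesGroup:
    """A labelled collection of reference sequences (or amplicons)."""

    label: str
    members: tuple
    status: str = "unknown"  # edible | poisonous | unknown

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValidationError(f"group {self.label!r} has no members")
        if self.status not in ("edible", "poisonous", "unknown"):
            raise ValidationError(f"group {self.label!r}: unknown status {self.status!r}")


@dataclass(frozen=True)
class EnzymeTreatment:
    """One or more enzymes applied together (a double digest is one treatment)."""

    enzymes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValidationError("treatment must name at least one enzyme")
        object.__setattr__(self, "enzymes", tuple(self.enzymes))

    @classmethod
    def parse(cls, text: str) -> "EnzymeTreatment":
        """Parse 'MslI' or 'HincII+HaeIII'."""
        return cls(tuple(p.strip() for p in text.split("+") if p.strip()))

    @property
    def name(self) -> str:
        return "+".join(self.enzymes)

    def resolve(self, catalog: Mapping[str, RestrictionEnzyme]) -> list[RestrictionEnzyme]:
        missing = [e for e in self.enzymes if e not in catalog]
        if missing:
            raise ValidationError(f"unknown enzyme(s) in treatment: {', '.join(missing)}")
        return [catalog[e] for e in self.enzymes]

    def __str__(self) -> str:
        return self.name


class CoverageError(ValueError):
    """No treatment set separates every group pair.

    Carries the best partial panel and the uncovered pairs.
    """

    def __init__(self, partial_panel, uncovered_pairs):
        self.partial_panel = list(partial_panel)
        self.uncovered_pairs = list(uncovered_pairs)
        pairs = "; ".join(f"{a} vs {b}" for a, b in self.uncovered_pairs)
        super().__init__(f"groups not separated by any treatment: {pairs}")


def default_treatments() -> list[EnzymeTreatment]:
    """The published assay's treatments: MslI, DdeI, HincII+HaeIII."""
    return [
        EnzymeTreatment(("MslI",)),
        EnzymeTreatment(("DdeI",)),
        EnzymeTreatment(("HincII", "HaeIII")),
    ]


def member_pattern(
    member: SequenceLike,
    treatment: EnzymeTreatment,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    gel: GelParams = GelParams(),
) -> BandPattern:
    """Virtual gel pattern of one sequence under one treatment."""
    frags = digest(member, treatment.resolve(catalog))
    return to_band_pattern(frags, resolution=gel.resolution, weak_threshold=gel.weak_threshold)


def _group_patterns(group, treatment, catalog, gel):
    return [member_pattern(m, treatment, catalog, gel) for m in group.members]


def _group_consistent(group, patterns, gel) -> bool:
    for (i, a), (j, b) in combinations(enumerate(patterns), 2):
        if patterns_distinguishable(a, b, gel.resolution):
            member = getattr(group.members[j], "id", f"member {j}")
            logger.warning(
                "group %s is internally inconsistent: member %s deviates",
                group.label,
                member,
            )
            return False
    return True


def treatment_separates(
    treatment: EnzymeTreatment,
    g1: SpeciesGroup,
    g2: SpeciesGroup,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    gel: GelParams = GelParams(),
) -> bool:
    """Does *treatment* reliably tell *g1* and *g2* apart on a gel?

    Requires (a) internal consistency — within each group all members'
    patterns are mutually indistinguishable (small intra-group indels are
    absorbed by the gel resolution) — and (b) every cross-group pair of
    patterns is distinguishable.  A group failing (a) yields False with a
    logged warning naming the discordant member.
    """
    if g1.label == g2.label:
        return False
    p1 = _group_patterns(g1, treatment, catalog, gel)
    p2 = _group_patterns(g2, treatment, catalog, gel)
    if not _group_consistent(g1, p1, gel) or not _group_consistent(g2, p2, gel):
        return False
    return all(
        patterns_distinguishable(a, b, gel.resolution) for a in p1 for b in p2
    )


def select_panel(
    treatments: Sequence[EnzymeTreatment],
    groups: Sequence[SpeciesGroup],
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    gel: GelParams = GelParams(),
) -> list[EnzymeTreatment]:
    """Greedy set-cover panel: every group pair separated by ≥1 treatment.

    Repeatedly picks the treatment separating the most not-yet-separated
    pairs; ties break deterministically on (fewer enzymes, lexicographic
    name).  Raises :class:`CoverageError` — carrying the best partial panel
    and the uncovered pairs — when no full cover exists.
    """
    if len(groups) < 2:
        raise ValidationError("panel selection needs at least two groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValidationError("group labels must be unique")
    pairs = list(combinations(groups, 2))
    separated_by = {
        t.name: {
            (a.label, b.label)
            for a, b in pairs
            if treatment_separates(t, a, b, catalog, gel)
        }
        for t in treatments
    }
    uncovered = {(a.label, b.label) for a, b in pairs}
    panel: list[EnzymeTreatment] = []
    while uncovered:
        best = min(
            treatments,
            key=lambda t: (
                -len(separated_by[t.name] & uncovered),
                len(t.enzymes),
                t.name,
            ),
        )
        gain = separated_by[best.name] & uncovered
        if not gain:
            raise CoverageError(panel, sorted(uncovered))
        panel.append(best)
        uncovered -= gain
    return panel


@dataclass(frozen=True)
class AssayKey:
    """An ordered decision key: treatments plus each group's expected pattern.

    Treatments are applied in panel order (the published key reads
    MslI → DdeI → HincII+HaeIII); a sample keeps a candidate label only while
    its pattern under each treatment is indistinguishable from that label's
    reference pattern.
    """

    treatments: tuple[EnzymeTreatment, ...]
    expected: Mapping[str, Mapping[str, BandPattern]]  # label -> treatment name -> pattern
    statuses: Mapping[str, str]
    gel: GelParams = GelParams()

    @property
    def labels(self) -> list[str]:
        return list(self.expected)


def build_key(
    panel: Sequence[EnzymeTreatment],
    groups: Sequence[SpeciesGroup],
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    gel: GelParams = GelParams(),
) -> AssayKey:
    """Compile a panel into a decision key, verifying pairwise coverage.

    Raises :class:`CoverageError` listing any group pair no panel treatment
    separates.  The reference pattern for each (group, treatment) is the
    pattern of the group's first member (groups must be internally
    consistent, which coverage checking enforces en route).
    """
    uncovered = [
        (a.label, b.label)
        for a, b in combinations(groups, 2)
        if not any(treatment_separates(t, a, b, catalog, gel) for t in panel)
    ]
    if uncovered:
        raise CoverageError(list(panel), uncovered)
    expected = {
        g.label: {
            t.name: member_pattern(g.members[0], t, catalog, gel) for t in panel
        }
        for g in groups
    }
    statuses = {g.label: g.status for g in groups}
    return AssayKey(
        treatments=tuple(panel), expected=expected, statuses=statuses, gel=gel
    )


Observation = Union[BandPattern, Sequence[float]]


def _observed_pattern(obs: Observation, gel: GelParams) -> BandPattern:
    if isinstance(obs, BandPattern):
        return obs
    return to_band_pattern(
        [float(s) for s in obs],
        resolution=gel.resolution,
        weak_threshold=gel.weak_threshold,
    )


def classify(
    sample: Union[SequenceLike, Mapping[str, Observation]],
    key: AssayKey,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
) -> str:
    """Route a sample through the key; returns a label or ``"undetermined"``.

    *sample* is either a sequence/amplicon (patterns are computed by in-silico
    digestion) or a mapping from treatment name to an observed gel pattern
    (a :class:`BandPattern`, or a plain list of band sizes as read off a
    gel).  A missing observation for a treatment the key needs raises a
    :class:`ValidationError` naming the treatment.
    """
    candidates = key.labels
    for t in key.treatments:
        if isinstance(sample, Mapping):
            if t.name not in sample:
                raise ValidationError(
                    f"sample provides no observation for treatment {t.name}"
                )
            pattern = _observed_pattern(sample[t.name], key.gel)
        else:
            pattern = member_pattern(sample, t, catalog, key.gel)
        candidates = [
            label
            for label in candidates
            if not patterns_distinguishable(
                pattern, key.expected[label][t.name], key.gel.resolution
            )
        ]
    return candidates[0] if len(candidates) == 1 else UNDETERMINED


def amplify_groups(
    groups: Sequence[SpeciesGroup],
    fwd,
    rev,
    max_len: int = 3000,
) -> list[SpeciesGroup]:
    """Map each group's members through in-silico PCR before digestion.

    RFLP patterns are read on the PCR product, not on the genomic template,
    so reference groups of templates are converted to groups of amplicons.
    Each member must yield exactly one product.
    """
    from .pcr import amplify

    out: list[SpeciesGroup] = []
    for g in groups:
        amplicons = []
        for m in g.members:
            products = amplify(m, fwd, rev, max_len=max_len)
            if len(products) != 1:
                raise ValidationError(
                    f"{getattr(m, 'id', '?')}: expected one product for "
                    f"{fwd.name}/{rev.name}, got {len(products)}"
                )
            amplicons.append(products[0])
        out.append(SpeciesGroup(label=g.label, members=tuple(amplicons), status=g.status))
    return out


def detect_contaminant(
    mixture: Iterable[SequenceLike],
    treatment: EnzymeTreatment,
    diagnostic_intact_size: float,
    catalog: Mapping[str, RestrictionEnzyme] = DEFAULT_CATALOG,
    gel: GelParams = GelParams(),
) -> bool:
    """Does the intact (undigested) band persist in a pooled sample?

    True iff at least one pooled member yields, after *treatment*, a fragment
    within gel resolution of ``diagnostic_intact_size`` — the signature of a
    poisonous-type sequence lacking the cut site amid a background of
    digestible edible species.  Monotone: adding members never flips
    True → False.
    """
    members = list(mixture)
    if not members:
        raise ValidationError("contaminant detection requires a non-empty pool")
    enzymes = treatment.resolve(catalog)
    for member in members:
        for length in digest(member, enzymes).fragment_lengths:
            if abs(length - diagnostic_intact_size) <= gel.resolution * max(
                length, diagnostic_intact_size
            ):
                return True
    return False
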