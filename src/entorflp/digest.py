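"""Restriction digest simulation on linear DNA.

A :class:`RestrictionEnzyme` couples a degenerate recognition pattern with
top- and bottom-strand cut offsets.  Digestion is modelled as complete: every
recognition site on either strand contributes a cut, a combined (double)
digest is the union of the single digests' cut sets, and the resulting
fragments partition the input.

The default catalog ships the four enzymes of the *Entoloma* assay with
REBASE-standard offsets:

======  ==========  ===============  =========
name    site        cut (top/bot)    end type
======  ==========  ===============  =========
MslI    CAYNNNNRTG  5/5              blunt
DdeI    CTNAG       1/4              5′ overhang
HincII  GTYRAC      3/3              blunt
HaeIII  GGCC        2/2              blunt
======  ==========  ===============  =========

All four are degenerate-palindromic, so each physical site is counted once;
the engine remains correct for non-palindromic user enzymes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .iupac import (
    DegeneratePattern,
    MatchMode,
    NucleotideSequence,
    ValidationError,
    find_matches,
)
from .pcr import Amplicon

__all__ = [
    "RestrictionEnzyme",
    "FragmentSet",
    "DEFAULT_CATALOG",
    "load_catalog",
    "parse_catalog",
    "find_cut_sites",
    "digest",
]

Digestible = Union[NucleotideSequence, Amplicon, str]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition pattern with cut offsets.

    ``cut_top`` is the number of recognition-site bases 5′ of the cut on the
    top strand; ``cut_bottom`` the same on the bottom strand, counted from the
    bottom strand's 5′ end (i.e. from the right edge of the site in top-strand
    coordinates).  Blunt cutters have ``cut_top == len - cut_bottom`` reversed
    symmetry; DdeI (C^TNA_G, 1/4) leaves a 3-nt 5′ overhang.
    """

    name: str
    recognition: DegeneratePattern
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if isinstance(self.recognition, str):
            object.__setattr__(self, "recognition", DegeneratePattern(self.recognition))
        n = len(self.recognition)
        if not (0 <= self.cut_top <= n and 0 <= self.cut_bottom <= n):
            raise ValidationError(
                f"{self.name}: cut offsets must lie within the recognition site"
            )

    @property
    def is_blunt(self) -> bool:
        return self.cut_top == self.cut_bottom

    @property
    def overhang(self) -> int:
        """Length of the single-stranded overhang left at each cut."""
        return abs(self.cut_bottom - self.cut_top)


@dataclass(frozen=True)
class FragmentSet:
    """Result of a complete digest of one linear sequence."""

    source_id: str
    source_length: int
    enzymes: tuple[str, ...]
    cut_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        cuts = tuple(sorted(set(self.cut_positions)))
        object.__setattr__(self, "cut_positions", cuts)
        if any(c <= 0 or c >= self.source_length for c in cuts):
            raise ValidationError("cut positions must lie strictly inside the sequence")

    @property
    def fragment_intervals(self) -> list[tuple[int, int]]:
        bounds = (0, *self.cut_positions, self.source_length)
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    @property
    def fragment_lengths(self) -> list[int]:
        """Fragment lengths, sorted descending (gel order)."""
        return sorted((b - a for a, b in self.fragment_intervals), reverse=True)

    def __len__(self) -> int:
        return len(self.cut_positions) + 1


DEFAULT_CATALOG_TEXT = """\
MslI\tCAYNNNNRTG\t5\t5
DdeI\tCTNAG\t1\t4
HincII\tGTYRAC\t3\t3
HaeIII\tGGCC\t2\t2
"""


def parse_catalog(text: str) -> dict[str, RestrictionEnzyme]:
    """Parse a plain-text enzyme catalog: NAME<TAB>MOTIF<TAB>CUT_TOP<TAB>CUT_BOTTOM."""
    catalog: dict[str, RestrictionEnzyme] = {}
    for n, line in enumerate(io.StringIO(text), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(f"catalog line {n}: expected 4 tab-separated fields")
        name, motif, top, bottom = parts
        if name in catalog:
            raise ValidationError(f"catalog line {n}: duplicate enzyme {name!r}")
        catalog[name] = RestrictionEnzyme(name, DegeneratePattern(motif), int(top), int(bottom))
    return catalog


def load_catalog(path=None) -> dict[str, RestrictionEnzyme]:
    """Load an enzyme catalog file, or the built-in four-enzyme default."""
    if path is None:
        return parse_catalog(DEFAULT_CATALOG_TEXT)
    with open(str(path)) as fh:
        return parse_catalog(fh.read())


DEFAULT_CATALOG = load_catalog()


def _residues_of(seq: Digestible) -> tuple[str, str]:
    if isinstance(seq, NucleotideSequence):
        return seq.id, seq.residues
    if isinstance(seq, Amplicon):
        return seq.id, seq.residues
    return "seq", NucleotideSequence(id="seq", residues=seq).residues


def find_cut_sites(
    seq: Digestible,
    enzyme: RestrictionEnzyme,
    mode: MatchMode = "subset",
) -> list[int]:
    """Sorted top-strand cut coordinates of one enzyme on a linear sequence.

    A + strand recognition at footprint start *i* cuts the top strand at
    ``i + cut_top``; a − strand recognition (reverse complement of the motif
    at *i*) cuts it at ``i + len - cut_bottom``.  Duplicate coordinates
    collapse; cuts at the extreme ends (coordinate 0 or len) are dropped as
    they release no fragment.
    """
    _, residues = _residues_of(seq)
    n = len(residues)
    m = len(enzyme.recognition)
    cuts: set[int] = set()
    for start, strand in find_matches(enzyme.recognition, residues, both_strands=True, mode=mode):
        if strand == "+":
            cuts.add(start + enzyme.cut_top)
            # Palindromic motifs match both strands at the same footprint;
            # the bottom-strand recognition implies its own top-strand cut.
            if enzyme.recognition.is_palindromic:
                cuts.add(start + m - enzyme.cut_bottom)
        else:
            cuts.add(start + m - enzyme.cut_bottom)
    return sorted(c for c in cuts if 0 < c < n)


def digest(
    seq: Digestible,
    enzymes: Sequence[RestrictionEnzyme] | Iterable[RestrictionEnzyme],
    mode: MatchMode = "subset",
) -> FragmentSet:
    """Complete single or combined digest; cut set is the union over enzymes."""
    enzymes = list(enzymes)
    if not enzymes:
        raise ValidationError("digest requires at least one enzyme")
    source_id, residues = _residues_of(seq)
    cuts: set[int] = set()
    for enz in enzymes:
        cuts.update(find_cut_sites(residues, enz, mode=mode))
    return FragmentSet(
        source_id=source_id,
        source_length=len(residues),
        enzymes=tuple(e.name for e in enzymes),
        cut_positions=tuple(sorted(cuts)),
    )
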