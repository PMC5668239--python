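"""Uncorrected p-distances on aligned sequences, with bootstrap errors.

The p-distance between two aligned sequences is the proportion of differing
sites among the comparable sites; it is deliberately uncorrected for multiple
substitutions, matching how closely related *Entoloma* ITS groups are
compared (e.g. clade-I vs *E. majaloides* at ~3.1%).

Gap handling
------------
``pairwise-deletion`` (and its synonym here, ``all-sites``): for each pair,
columns where either member carries a gap or an ambiguity code are excluded
from the comparable-site count.  ``complete-deletion``: columns containing a
gap/ambiguity in *any* member of the alignment are removed once, before any
pair is compared.  The between-group mean's standard error is estimated by a
site (column) bootstrap with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .iupac import NucleotideSequence, ValidationError

__all__ = [
    "Alignment",
    "DistanceEstimate",
    "p_distance",
    "group_mean_distance",
    "DEFAULT_BOOTSTRAP_REPLICATES",
    "DEFAULT_BOOTSTRAP_SEED",
]

DEFAULT_BOOTSTRAP_REPLICATES = 500
DEFAULT_BOOTSTRAP_SEED = 20171102

GAP = "-"
_CONCRETE = frozenset("ACGT")

GapMode = str  # "pairwise-deletion" | "complete-deletion" | "all-sites"


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences; the gap symbol is ``-``."""

    members: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ValidationError("an alignment needs at least two members")
        lengths = {len(_aligned_residues(m)) for m in self.members}
        if len(lengths) != 1:
            raise ValidationError(f"aligned members differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(_aligned_residues(self.members[0]))


def _aligned_residues(member) -> str:
    if isinstance(member, NucleotideSequence):
        return member.residues
    return member.upper().replace("U", "T")


@dataclass(frozen=True)
class DistanceEstimate:
    p: float
    se: float
    n_sites: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 or self.se < 0 or self.n_sites < 1:
            raise ValidationError("invalid distance estimate")

    @property
    def percent(self) -> float:
        return 100.0 * self.p


def _comparable(a: str, b: str) -> bool:
    return a in _CONCRETE and b in _CONCRETE


def _pair_counts(a: str, b: str, columns=None) -> tuple[int, int]:
    """(differences, comparable sites) over the given column indices."""
    idx = range(len(a)) if columns is None else columns
    diffs = comp = 0
    for i in idx:
        x, y = a[i], b[i]
        if _comparable(x, y):
            comp += 1
            if x != y:
                diffs += 1
    return diffs, comp


def p_distance(
    a: NucleotideSequence | str,
    b: NucleotideSequence | str,
    gap_mode: GapMode = "all-sites",
) -> DistanceEstimate:
    """Uncorrected distance between two aligned sequences (se is 0).

    Columns where either sequence has a gap or an ambiguity code are excluded
    under every mode; ``complete-deletion`` for a single pair coincides with
    pairwise deletion and is accepted for interface symmetry.
    """
    ra, rb = _aligned_residues(a), _aligned_residues(b)
    if len(ra) != len(rb):
        raise ValidationError("sequences are not aligned to equal length")
    if gap_mode not in ("pairwise-deletion", "complete-deletion", "all-sites"):
        raise ValidationError(f"unknown gap mode {gap_mode!r}")
    diffs, comp = _pair_counts(ra, rb)
    if comp == 0:
        raise ValidationError("no comparable sites between the two sequences")
    return DistanceEstimate(p=diffs / comp, se=0.0, n_sites=comp)


def _complete_deletion_columns(rows: list[str]) -> list[int]:
    return [
        i for i in range(len(rows[0])) if all(r[i] in _CONCRETE for r in rows)
    ]


def group_mean_distance(
    group_a,
    group_b,
    gap_mode: GapMode = "all-sites",
    n_bootstrap: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> DistanceEstimate:
    """Mean between-group p-distance with a site-bootstrap standard error.

    The point estimate is the arithmetic mean of p over all cross-group
    pairs.  The SE resamples alignment columns with replacement
    (*n_bootstrap* replicates, seeded) and takes the standard deviation of
    the replicate means; replicate pairs with zero comparable sites are
    dropped from that replicate's mean.
    """
    rows_a = [_aligned_residues(m) for m in group_a]
    rows_b = [_aligned_residues(m) for m in group_b]
    if not rows_a or not rows_b:
        raise ValidationError("both groups must be non-empty")
    length = {len(r) for r in rows_a + rows_b}
    if len(length) != 1:
        raise ValidationError("groups must come from a common alignment")
    ncols = length.pop()

    if gap_mode == "complete-deletion":
        base_columns = _complete_deletion_columns(rows_a + rows_b)
        if not base_columns:
            raise ValidationError("complete deletion removed every column")
    else:
        base_columns = list(range(ncols))

    def mean_p(columns) -> float | None:
        values = []
        for ra, rb in product(rows_a, rows_b):
            diffs, comp = _pair_counts(ra, rb, columns)
            if comp:
                values.append(diffs / comp)
        return float(np.mean(values)) if values else None

    point = mean_p(base_columns)
    if point is None:
        raise ValidationError("no comparable sites in any cross-group pair")
    total_comp = sum(
        _pair_counts(ra, rb, base_columns)[1] for ra, rb in product(rows_a, rows_b)
    )
    n_pairs = len(rows_a) * len(rows_b)

    se = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        cols = np.asarray(base_columns)
        replicates = []
        for _ in range(n_bootstrap):
            resampled = rng.choice(cols, size=cols.size, replace=True)
            m = mean_p(resampled.tolist())
            if m is not None:
                replicates.append(m)
        if len(replicates) > 1:
            se = float(np.std(replicates, ddof=1))

    return DistanceEstimate(p=point, se=se, n_sites=max(1, total_comp // n_pairs))
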