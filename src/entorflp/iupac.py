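"""IUPAC nucleotide alphabet semantics, degenerate pattern matching and FASTA I/O.

Every other module builds on the primitives here: sequences are stored
uppercase over the 15-letter IUPAC alphabet (``U`` is normalised to ``T`` on
input), patterns such as the MslI recognition site ``CAYNNNNRTG`` are matched
per-position against base sets, and both-strand scanning deduplicates sites
for patterns that are their own reverse complement.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "IUPAC_SETS",
    "COMPLEMENT",
    "NucleotideSequence",
    "DegeneratePattern",
    "ValidationError",
    "FastaParseError",
    "complement",
    "reverse_complement",
    "matches",
    "find_matches",
    "expand_pattern",
    "read_fasta",
    "write_fasta",
]

#: Base set denoted by each IUPAC symbol.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Symbol-level complement (complements the underlying base set).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(COMPLEMENT)

MatchMode = Literal["subset", "intersection"]


class ValidationError(ValueError):
    """A residue string violates the IUPAC alphabet or a type invariant."""


class FastaParseError(ValueError):
    """A FASTA file is structurally malformed."""


def normalize_residues(residues: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and validate against the 15-symbol alphabet.

    Raises :class:`ValidationError` naming the first illegal symbol and its
    0-based position.
    """
    if not residues:
        raise ValidationError(f"{context}: residue string is empty")
    up = residues.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise ValidationError(
                f"{context}: illegal symbol {ch!r} at position {i}"
            )
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence over the IUPAC alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, context=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, id_suffix: str = "_rc") -> "NucleotideSequence":
        return NucleotideSequence(
            id=self.id + id_suffix,
            residues=reverse_complement(self.residues),
            description=self.description,
        )


@dataclass(frozen=True)
class DegeneratePattern:
    """A degenerate motif such as MslI's CAYNNNNRTG.

    Cut positions are *not* part of the pattern; they belong to
    :class:`entorflp.digest.RestrictionEnzyme`.
    """

    motif: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "motif", normalize_residues(self.motif, context="pattern")
        )

    def __len__(self) -> int:
        return len(self.motif)

    @property
    def is_palindromic(self) -> bool:
        """True when the motif equals its own reverse complement symbol-wise."""
        return self.motif == reverse_complement(self.motif)

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(reverse_complement(self.motif))


def complement(residues: str) -> str:
    """Symbol-wise IUPAC complement (not reversed)."""
    normalize_residues(residues)
    return residues.upper().replace("U", "T").translate(_COMPLEMENT_TABLE)


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement; an involution on all 15 symbols."""
    return complement(residues)[::-1]


def _as_pattern(pattern: DegeneratePattern | str) -> DegeneratePattern:
    return pattern if isinstance(pattern, DegeneratePattern) else DegeneratePattern(pattern)


def matches(
    pattern: DegeneratePattern | str,
    word: str,
    mode: MatchMode = "subset",
) -> bool:
    """Does *word* lie in the set of sequences denoted by *pattern*?

    For concrete words (A/C/G/T only) this is plain membership: at every
    position the word's base must be in the pattern symbol's base set.
    Ambiguity codes in the word are resolved by *mode*:

    - ``"subset"`` (default): the word symbol's entire base set must be
      contained in the pattern symbol's set.  Conservative -- an ``N`` in a
      deposited sequence never produces a phantom restriction site.
    - ``"intersection"``: any shared base suffices.
    """
    pat = _as_pattern(pattern)
    w = normalize_residues(word, context="word")
    if len(w) != len(pat):
        raise ValueError(
            f"length mismatch: pattern {len(pat)} vs word {len(w)}"
        )
    if mode == "subset":
        return all(
            IUPAC_SETS[b] <= IUPAC_SETS[p] for p, b in zip(pat.motif, w)
        )
    if mode == "intersection":
        return all(
            IUPAC_SETS[b] & IUPAC_SETS[p] for p, b in zip(pat.motif, w)
        )
    raise ValueError(f"unknown match mode {mode!r}")


def _scan(motif: DegeneratePattern, residues: str, mode: MatchMode) -> Iterator[int]:
    m = len(motif)
    for i in range(len(residues) - m + 1):
        if matches(motif, residues[i : i + m], mode=mode):
            yield i


def find_matches(
    pattern: DegeneratePattern | str,
    seq: NucleotideSequence | str,
    both_strands: bool = True,
    mode: MatchMode = "subset",
) -> list[tuple[int, str]]:
    """All footprint start positions of *pattern* on *seq*.

    Returns ``(start, strand)`` pairs where *start* is the 0-based position of
    the footprint's leftmost base on the + strand.  A − strand hit at *start*
    means the reverse complement of the pattern occurs at *start* on the
    + strand.  For self-reverse-complementary patterns (all four shipped
    enzymes) each physical site is reported exactly once, on the + strand.
    """
    pat = _as_pattern(pattern)
    residues = seq.residues if isinstance(seq, NucleotideSequence) else normalize_residues(seq)
    hits: list[tuple[int, str]] = [(i, "+") for i in _scan(pat, residues, mode)]
    if both_strands and not pat.is_palindromic:
        rc = pat.reverse_complement()
        hits.extend((i, "-") for i in _scan(rc, residues, mode))
    return sorted(hits)


def expand_pattern(pattern: DegeneratePattern | str) -> set[str]:
    """Brute-force expansion of a degenerate motif into all concrete words.

    Exponential in the number of ambiguity codes; intended for catalogues of
    short recognition sites and for oracle checks.
    """
    pat = _as_pattern(pattern)
    words = [""]
    for sym in pat.motif:
        words = [w + b for w in words for b in sorted(IUPAC_SETS[sym])]
    return set(words)


# --------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Order is preserved.  Raises :class:`FastaParseError` (naming the line) for
    structural problems and :class:`ValidationError` for illegal residues or
    duplicate ids.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    # Structural pre-scan with line numbers; SimpleFastaParser silently skips
    # leading junk and empty records, which a validating reader must not.
    first_content = next(
        (n for n, ln in enumerate(lines, 1) if ln.strip()), None
    )
    if first_content is None:
        raise FastaParseError(f"{path}: file contains no records")
    if not lines[first_content - 1].startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_content}: expected '>' header before sequence data"
        )
    header_line = None
    has_residues = False
    for n, ln in enumerate(lines, 1):
        if ln.startswith(">"):
            if header_line is not None and not has_residues:
                raise FastaParseError(
                    f"{path}: line {header_line}: record has no sequence lines"
                )
            if not ln[1:].strip():
                raise FastaParseError(f"{path}: line {n}: empty FASTA header")
            header_line, has_residues = n, False
        elif ln.strip():
            has_residues = True
    if header_line is not None and not has_residues:
        raise FastaParseError(
            f"{path}: line {header_line}: record has no sequence lines"
        )

    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, residues in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            seq_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if seq_id in seen:
                raise ValidationError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            records.append(NucleotideSequence(id=seq_id, residues=residues, description=desc))
    return records


def write_fasta(
    path,
    sequences: Iterable[NucleotideSequence],
    width: int = 70,
) -> None:
    """Write sequences as wrapped FASTA; round-trips through :func:`read_fasta`."""
    with open(str(path), "w") as fh:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            if width <= 0:
                fh.write(seq.residues + "\n")
            else:
                for i in range(0, len(seq.residues), width):
                    fh.write(seq.residues[i : i + width] + "\n")
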