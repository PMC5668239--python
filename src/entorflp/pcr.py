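"""In-silico PCR: primer-site location and amplicon extraction.

Reproduces the two assays used for *Entoloma* identification: the full-length
ITS amplification (ITS1-F/ITS4, ~1 kb product) and the short ITS2 amplicon
(Short-F/Short-R, 214 bp) that carries the diagnostic MslI site and survives
cooking and gastric digestion.

Product length follows standard PCR semantics: both primer footprints are
included, so the product spans from the 5′ end of the forward footprint to
the 5′ end of the reverse footprint on the opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .iupac import (
    IUPAC_SETS,
    MatchMode,
    NucleotideSequence,
    ValidationError,
    normalize_residues,
    reverse_complement,
)

__all__ = ["Primer", "Amplicon", "find_primer_sites", "amplify", "PRESETS"]


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5′→3′.

    ``max_mismatch`` mismatches are tolerated outside the ``three_prime_exact``
    terminal bases, which must match exactly (polymerase extension is most
    sensitive to 3′ mispairing).  The assay presumes exact priming by default.
    """

    name: str
    residues: str
    max_mismatch: int = 0
    three_prime_exact: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, context=self.name)
        )
        if self.max_mismatch < 0 or self.max_mismatch >= len(self.residues):
            raise ValidationError(
                f"{self.name}: max_mismatch must be in [0, primer length)"
            )
        if not 0 <= self.three_prime_exact <= len(self.residues):
            raise ValidationError(
                f"{self.name}: three_prime_exact must be within the primer length"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited product: ``[start, end)`` on the template's + strand.

    ``residues`` is always the + strand slice of the template.  ``strand``
    records the product orientation: ``+`` when the forward primer annealed to
    the + strand; ``-`` when the primers primed the opposite orientation, in
    which case :attr:`product_seq` (the molecule as synthesised, starting with
    the forward primer) is the reverse complement of ``residues``.
    """

    template_id: str
    start: int
    end: int
    residues: str
    fwd_primer: str
    rev_primer: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.residues):
            raise ValidationError("amplicon coordinates do not match residue length")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def product_seq(self) -> str:
        return self.residues if self.strand == "+" else reverse_complement(self.residues)

    @property
    def id(self) -> str:
        return f"{self.template_id}:{self.start}-{self.end}({self.strand})"

    def as_sequence(self) -> NucleotideSequence:
        return NucleotideSequence(id=self.id, residues=self.residues)


def _mismatch_profile(primer: str, window: str, mode: MatchMode) -> list[bool]:
    """Per-position agreement of a primer with a template window.

    A position agrees when the template symbol's base set is compatible with
    the primer symbol's set under *mode* (subset: template set contained in
    primer set — an N in the template never silently matches a concrete
    primer base).
    """
    out = []
    for p, t in zip(primer, window):
        if mode == "subset":
            out.append(IUPAC_SETS[t] <= IUPAC_SETS[p])
        else:
            out.append(bool(IUPAC_SETS[t] & IUPAC_SETS[p]))
    return out


def find_primer_sites(
    template: NucleotideSequence,
    primer: Primer,
    mode: MatchMode = "subset",
) -> list[tuple[int, str, int]]:
    """All annealing sites of *primer* on either strand of *template*.

    Returns ``(start, strand, mismatch_count)`` triples; *start* is the
    0-based + strand coordinate of the footprint's leftmost base.  A hit
    requires at most ``primer.max_mismatch`` total mismatches and none in the
    ``three_prime_exact`` 3′-terminal bases (the footprint's right end for
    + hits, left end for − hits).
    """
    residues = template.residues
    plen = len(primer)
    if plen >= len(residues):
        raise ValidationError(
            f"primer {primer.name} is not shorter than template {template.id}"
        )
    fwd = primer.residues
    rev = reverse_complement(primer.residues)
    hits: list[tuple[int, str, int]] = []
    for i in range(len(residues) - plen + 1):
        window = residues[i : i + plen]
        # + strand: primer 5' end at footprint start, 3' end at the right.
        ok = _mismatch_profile(fwd, window, mode)
        mm = ok.count(False)
        if mm <= primer.max_mismatch and (
            primer.three_prime_exact == 0 or all(ok[plen - primer.three_prime_exact :])
        ):
            hits.append((i, "+", mm))
        # − strand: compare the reverse complement; 3' end maps to the left.
        ok = _mismatch_profile(rev, window, mode)
        mm = ok.count(False)
        if mm <= primer.max_mismatch and (
            primer.three_prime_exact == 0 or all(ok[: primer.three_prime_exact])
        ):
            hits.append((i, "-", mm))
    return hits


def amplify(
    template: NucleotideSequence,
    fwd: Primer,
    rev: Primer,
    max_len: int = 3000,
    mode: MatchMode = "subset",
) -> list[Amplicon]:
    """All products of the primer pair on *template*, shorter than *max_len*.

    Both orientations are considered: the forward primer priming the + strand
    with the reverse primer on −, and the mirror arrangement.  Each pairing of
    an upstream forward footprint with a downstream (opposite strand) reverse
    footprint whose span is at most *max_len* and whose footprints do not
    overlap yields one :class:`Amplicon`.  Sorted by start, then length.
    """
    if max_len <= 0:
        raise ValidationError("max_len must be positive")
    fwd_hits = find_primer_sites(template, fwd, mode)
    rev_hits = find_primer_sites(template, rev, mode)
    products: list[Amplicon] = []

    def pair(left_hits, right_hits, left_primer, right_primer, strand):
        llen, rlen = len(left_primer), len(right_primer)
        for ls, lstrand, _ in left_hits:
            if lstrand != "+":
                continue
            for rs, rstrand, _ in right_hits:
                if rstrand != "-":
                    continue
                start, end = ls, rs + rlen
                if rs < ls + llen:  # overlapping or inverted footprints
                    continue
                if end - start > max_len:
                    continue
                products.append(
                    Amplicon(
                        template_id=template.id,
                        start=start,
                        end=end,
                        residues=template.residues[start:end],
                        fwd_primer=fwd.name,
                        rev_primer=rev.name,
                        strand=strand,
                    )
                )

    pair(fwd_hits, rev_hits, fwd, rev, "+")
    # Mirror orientation: reverse primer extends along +, forward along −.
    pair(rev_hits, fwd_hits, rev, fwd, "-")
    return sorted(products, key=lambda a: (a.start, a.end - a.start, a.strand))


#: Published primer pairs for the two assays.  ITS1-F (Gardes & Bruns) and
#: ITS4 (White et al.) delimit the full ITS1–5.8S–ITS2 barcode; Short-F/Short-R
#: delimit the 214-bp ITS2 fragment spanning the diagnostic MslI site.
PRESETS: dict[str, tuple[Primer, Primer]] = {
    "ITS-full": (
        Primer("ITS1-F", "CTTGGTCATTTAGAGGAAGTAA"),
        Primer("ITS4", "TCCTCCGCTTATTGATATGC"),
    ),
    "ITS2-short": (
        Primer("Short-F", "GCTCTTCTTAAATGCATTAGC"),
        Primer("Short-R", "TCGCTTCGTCAACCTG"),
    ),
}
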