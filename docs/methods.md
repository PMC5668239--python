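# Methods

## The identification problem

Edible *Entoloma sarcopum* and three poisonous *E. rhodopolium*-related
species (*E. lacus*, *E. subrhodopolium*, *E. pseudorhodopolium*) are hard to
tell apart morphologically but carry diagnostic differences in their ITS
barcode. PCR-RFLP turns those differences into gel band patterns: amplify a
shared region, digest with chosen restriction enzymes, and compare fragment
sizes. The pivotal polymorphism is inside the degenerate MslI recognition
site CAYNN|NNRTG: the edible taxon carries CATTG|GTATG (a valid
concretisation, so MslI cuts) while the poisonous clades carry CTYTG|RTATG
(position 2 is T, not the required A, so MslI cannot cut regardless of how
the Y/R ambiguities resolve). Two amplicons are used: the full ITS region
(ITS1-F/ITS4, 1,075 bp in these taxa) for fresh material, and a 214-bp ITS2
fragment (Short-F/Short-R) spanning the MslI site for cooked or gastric-
digested residues where only short DNA survives.

## Sequence model and matching semantics

Sequences are strings over the 15-letter IUPAC alphabet, stored uppercase
with U normalised to T. Coordinates are 0-based, half-open everywhere.
A degenerate pattern matches a concrete word when every word base lies in
the corresponding pattern symbol's base set. When the *template* itself
contains ambiguity codes, the default "subset" mode demands that the
template symbol's whole base set be covered by the pattern symbol — a
conservative rule under which an N or R in a deposited sequence can never
conjure a phantom cut site. An "intersection" mode (any shared base) is
available for exploratory use. For a safety-oriented assay a falsely
predicted cut is worse than a missed one; that asymmetry drove the default.

## In-silico PCR

A primer anneals where it matches the template within `max_mismatch`
mismatches and exactly in its `three_prime_exact` terminal bases (default 3;
polymerase extension is most sensitive to 3′ mispairing). Defaults assume
exact priming (`max_mismatch = 0`), as the assay's primers were designed to
be invariant across the target taxa; tolerance is exposed for degraded
material. Products span from the 5′ end of the forward footprint to the 5′
end of the reverse footprint, so both primers are included — this is the
convention under which the short product is exactly 214 nt. Both template
orientations are searched; products found on the − strand are reported with
+ strand coordinates and a strand flag. All pairings within `max_len`
(default 3000) are returned; non-overlapping footprints are required.

## Restriction digestion

An enzyme is a degenerate recognition pattern plus two cut offsets, both
expressed as top-strand coordinates within the site: `cut_top` for the top
strand and `cut_bottom` for the bottom strand (equal offsets = blunt ends).
The shipped catalog (editable TSV: name, motif, cut_top, cut_bottom):

| enzyme | site | offsets | ends |
|---|---|---|---|
| MslI | CAYNNNNRTG | 5/5 | blunt |
| DdeI | CTNAG | 1/4 | 3-nt 5′ overhang |
| HincII | GTYRAC | 3/3 | blunt |
| HaeIII | GGCC | 2/2 | blunt |

Digestion is complete (every site cuts, no partials), substrates are linear,
and a combined digest's cut set is the union of the single digests'.
Both strands are scanned; for self-reverse-complementary patterns (all four
above) each physical site is counted once. Fragment lengths are measured
between consecutive top-strand cuts. One consequence worth knowing: for
sticky-end cutters the two *terminal* fragments of a molecule shift by the
overhang length (3 nt for DdeI) when the same molecule is digested as its
reverse complement; internal fragments are strand-invariant, and on a 3%
agarose gel a 3-nt shift is invisible. Methylation sensitivity, star
activity and circular substrates are out of scope.

## Virtual gel

Fragments within a relative tolerance of each other co-migrate and merge
into one band reported at the length-weighted mean size; bands below a
weak threshold are flagged weak. Defaults: `resolution = 0.05`
(≈ agarose sizing accuracy) and `weak_threshold = 150` bp. The threshold is
a judgment call — small fragments (65–146 bp here) smear and are not scored
diagnostically, while the smallest diagnostic band in the reference set is
192 bp — and both parameters are configurable. Two patterns are
distinguishable when their major (non-weak) bands cannot be matched
one-to-one within tolerance; with both lists sorted descending, greedy
positional pairing is equivalent to optimal bipartite matching for these
band counts (verified against a brute-force permutation oracle in tests).
Weak bands never enter comparisons, matching how the gels are read.

## Assay design and classification

A treatment (one enzyme or a double digest) *separates* two species groups
when every member's pattern within a group is mutually indistinguishable
(internal consistency — small intra-species indels are absorbed by gel
resolution) and every cross-group pattern pair is distinguishable. Panel
selection is greedy set cover over unordered group pairs: repeatedly take
the treatment separating the most uncovered pairs, breaking ties on fewer
enzymes, then name; if no full cover exists the error carries the best
partial panel and the uncovered pairs. The decision key applies treatments
in the order given — the published key reads MslI → DdeI → HincII+HaeIII —
and a sample retains a candidate label only while its pattern matches that
label's reference pattern under each treatment; a unique survivor is the
call, otherwise "undetermined". Observed gel readings (band-size lists) are
accepted in place of sequences. On the shipped reference panel the greedy
cover is [DdeI, HincII+HaeIII] (DdeI alone separates five of six pairs);
the three-treatment published order is equally self-consistent and is the
default in the CLI.

Contaminant detection models the cooked-mixture screen: a pool is positive
when any member retains a fragment within gel resolution of the intact
amplicon size after digestion (a poisonous-type molecule that MslI could not
cut). The test is monotone in pool membership. Edibility statuses are
metadata; nothing in the package asserts that a sample is safe.

## p-distances

The uncorrected p-distance is the fraction of differing sites among
comparable sites of two aligned sequences. Columns where either member has a
gap or ambiguity are excluded ("all-sites"/"pairwise-deletion");
"complete-deletion" removes columns containing a gap or ambiguity in any
alignment member before any pair is compared. Between-group means average
all cross-group pairs; the standard error resamples alignment columns with
replacement (default 500 replicates, seeded — default seed 20171102).
Alignments are consumed, not computed; use any external aligner.

## Synthetic fixtures: what they show and what they do not

No deposited sequences ship with the package; the fixture generator builds
synthetic stand-ins. Backgrounds are uniform over A/C/G/T with *motif
avoidance*: each base is chosen so it completes no catalog recognition site,
and assembled templates are verified so the only enzyme sites present are
the planted ones (junction-spawned sites trigger resampling). The shipped
reference panel plants primer footprints and enzyme sites at coordinates
chosen so that the four synthetic species reproduce the assay's published
geometry: 1,075-bp full and 214-bp short amplicons; DdeI majors 366/296/250
(edible-like) and 690 (lacus-like) with sub-150-bp weak bands; HincII+HaeIII
largest fragments 802/645/645/502; an edible-like MslI digest with two large
fragments plus an 80-bp fragment. Within-group length polymorphism is
emulated by a 9-nt insertion and a 1-nt deletion in members 2 and 3, placed
in background inside a window that lies within a large fragment of every
treatment (and outside the short-amplicon region, which real ITS2 conserves
across these taxa). The p-distance fixture plants 25 between-group and 2
private substitutions per member on disjoint sites of a 926-column
alignment, so every cross pair differs at 29/926 ≈ 3.13% of sites — the
magnitude separating the real sister taxa. The default fixture seed is
20171102.

Passing tests on these fixtures demonstrate that the *machinery* is correct
— matching, digestion, band logic, set cover, key routing, bootstrap — under
exactly the band geometry the assay exploits. They do not demonstrate
robustness to features real ITS data can show and the generator omits:
substitution-model heterogeneity, chance restriction sites in real
backgrounds, intra-species SNPs outside the planted sites, primer-binding
variation, or incomplete digestion (a known wet-lab caveat, deliberately not
modelled). Validating against deposited reference accessions requires
network access via `entorflp.fetch` and an external aligner.

## Numerical and degenerate-input choices

- Duplicate sequence ids, empty records, and illegal symbols are hard
  errors with the offending line/position named.
- Cut coordinates at 0 or sequence length are dropped (they release no
  fragment); duplicate coordinates collapse.
- Band merging is single-linkage in descending size order and idempotent.
- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  template assembly and indel placement retry with fresh draws from the same
  generator stream, so results are reproducible per seed.
- Greedy panel selection is deterministic, including tie-breaks.
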