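# Methods

## Problem setting and model

Human mitochondrial haplogroups are clades of maternal lineages defined by
shared variants relative to the rCRS (16,569 bp, 1-based coordinates,
position 3107 a historical placeholder). A haplogroup tree assigns each
branch a list of defining variants in Phylotree notation; the *cumulative
profile* of a haplogroup is the accumulation of branch variants along the
root-to-node path with two path rules: a `!` token reverts its site to the
reference state and removes the matching ancestral variant, and a later
substitution at an already-mutated position replaces the recorded derived
state. Profiles handed to the classifier therefore contain only literal
variants; all back-mutation algebra is resolved at profile-construction
time, which keeps the identity computation pure set arithmetic.

A sample is a set of called variants `Vs` plus the union `R` of reference
ranges its fragments cover. The ranking statistic is the fragment-range-
aware variant identity `(Vp − Vm)/Vs`: `Vp` profile variants present in
the sample, `Vm` profile variants absent from the sample *whose positions
lie inside `R`*. Restricting `Vm` to covered ranges is the core modelling
assumption for fragmented data: absence of evidence outside the sequenced
ranges is not evidence of absence. Haplogroups sharing the four highest
distinct identity values form Rank Groups 1–4; identities are compared as
exact rationals (`fractions.Fraction`) because rank-group membership is
defined by equality, and float ties would split or merge groups
spuriously.

Within a rank group, candidates are ordered by the frequency score
`Σ He(g,v)/H(g) + Σ Hm(g,v)/H(g)` over the sample's extra and missing
variants. The score is support, not penalty — a high score means the
sample's private variants are haplotypes already observed for that
haplogroup — so ordering is descending, with ties broken by `H(g)`
descending and then natural name order (numeric segments compared
numerically, so H2 < H10). `Hm(g,v)` is read as "samples of `g` recorded
as *lacking* the profile variant `v`", the reading symmetric to `He`'s
role; the alternative reading ("carrying `v`") would double-count `He`.

Samples with `Vs = 0` (reference-identical) have undefined identity; they
are ranked by ascending `Vm` instead, so a reference-identical sample
still classifies toward the shallow-profile clades rather than erroring.
Identity ties beyond the fourth distinct value are dropped and counted in
the report (`dropped_ties`).

## Alignment and variant calling

Fragments are located on a doubled reference (the genome is circular; the
control region spans the origin) by exact 13-mer diagonal voting, then
aligned inside a padded window with Biopython's C `PairwiseAligner`
configured as an affine-gap global aligner with free reference end gaps
(`end_deletion_score = 0`): the Gotoh recurrence with a gap of length *L*
costing `open + (L−1)·extend`. Queries of ≥ 80 % reference length skip
seeding and align against the single reference. The aligner's optimality
is checked in the test suite and acceptance script against an
independently written brute-force three-matrix DP on random pairs.

Default scores are match +1, mismatch −1, gap open −4, gap extend −1 —
conventional values for high-identity mtDNA fragments, exposed in
`AlignParams`. Tie-breaks use the aligner's deterministic first
traceback; any placement ambiguity is absorbed by normalization, which
right-shifts indels to their 3′-most equivalent placement before naming
(`315.1C` style). Substitutions are classed transition/transversion by
purine–pyrimidine partnership; IUPAC-ambiguous query bases produce no
call; covered ranges crossing the origin split into two intervals.

The default hotspot mask drops calls at positions {3107, 16519, 309, 315,
523, 524} — the placeholder plus the common mtDNA hypervariable indel
hotspots. The mask is positional and fully configurable; no claim is made
that it replicates any particular server's ignore list.

Overlapping fragments that disagree on a position's state (different
derived states, or variant vs reference) raise a conflict error naming
the position and fragments; a fragment scoring below 50 % of its
perfect-match score is rejected with a warning rather than polluting the
profile.

## Haplotype database construction

The database is rebuilt from scratch in each of (default) three passes of
self-classification: pass 1 uses identity alone, later passes use the
previous pass's frequencies. After each pass every haplogroup tied in a
sample's Rank Group 1 is credited with full weight (`H`, and `He`/`Hm`
per extra/missing variant). Records shorter than 400 bp are filtered out
(boundary inclusive); identical sequences under different ids count as
distinct samples; control-region and genomic records pool into the same
tables.

Under the default all-of-Rank-Group-1 credit rule the tables are a fixed
point after the first pass — scores order candidates within a rank group
but never change Rank Group 1 membership — and the acceptance script
verifies this. The `credit_policy="top_scored"` option credits only the
maximal-score subset of Rank Group 1; that is the reading under which
repeated prediction runs with regenerated scores actually sharpen the
tables, and both policies are exposed (with `credit_groups` and
`fractional` weighting knobs) rather than asserting either as canonical.

## Tracking

Narrowing prefers the scored subset of Rank Group 1 (score > 0), capped
at the top five scored candidates, and reports their MRCA. Amplicon
proposal is greedy partition refinement: among panel amplicons containing
uncovered discriminating variants, repeatedly pick the one splitting the
current candidate partition into the most classes (ties by panel order)
until the partition is discrete or no amplicon helps. With candidate sets
capped at five, greedy set cover is optimal or within one amplicon of
optimal and — unlike an ILP — deterministic and dependency-free.

A track ends the loop when Rank Group 1 narrows to one haplogroup.
Candidates forming an ancestor–descendant chain that no panel amplicon
can split finish at the deepest member (the verified-MRCA endpoint);
candidates that are profile-identical or whose discriminators lie outside
the panel stall with a flag. Every track either strictly shrinks the
candidate set, finishes, or stalls, so termination is guaranteed (a
10-track budget backstops the simulation).

The default first-track panel is four tiled CR amplicons (16024–16365,
16268–16569, 1–285, 220–576); the default coding panel tiles 577–16023
with 400 bp amplicons overlapping 40 bp. Real primer panels load from a
4-column TSV and may span the origin.

## Synthetic data

The packaged reference is a deterministic *synthetic* 16,569 bp sequence
with mtDNA-like composition, `N` at 3107 and homopolymer tracts at the
rCRS landmark positions — clearly labelled as a stand-in; every entry
point accepts a real rCRS FASTA.

`generate_toy_tree` grows nomenclature-style trees (A, A1, A1a, …) whose
branches carry 1–3 variants (80 % transitions, 10 % transversions, 10 %
indels placed only at 3′-most positions so reconstruction and re-calling
round-trip exactly), ~40 % of them in the CR, with top-level clades forced
to carry at least one CR variant. Each branch introduces at least one
fresh-position variant, so cumulative profiles are unique unless
CR-ambiguous sibling pairs are requested (siblings differing only at
coding positions — the multi-candidate case). Corpora contain CR
sequences and few-kb partial-genome windows per haplogroup, with one
recurrent private site per haplogroup carried by ~40 % of its samples —
the recurrence that gives the frequency score its discriminating power.
The damage model (terminal C→T / G→A with exponential positional decay,
e-folding 3 bases) defaults to rate 0: the realistic input to this kind
of tool is a PCR consensus sequence in which deamination is largely
averaged out, and the damage knob exists for stress-testing, not as a
claimed aDNA error model.

What passing tests on this synthetic world does *not* show: performance
on real Phylotree topology (5,434 named haplogroups with pass-through
structural nodes, recurrent mutations and back-mutation-rich paths), real
GenBank corpus composition, or real laboratory error modes (contamination,
jumping PCR, heteroplasmy). The structural queries expose both countings
of "sub-haplogroup level" (`skip_structural`) precisely because real
nomenclature trees mix named clades with structural junctions.

## Problem sizes and numerical choices

The test suite and acceptance script run on seeded trees of 16–50
haplogroups, corpora of ~100 records, and 200 random aligner-oracle pairs
of length ≤ 40 — sizes at which every quantity is exactly checkable
(identity values as rationals, DB counts as integers, simulation tables
byte-reproducible across runs). All randomness flows from explicit seeds;
classification, DB construction and tracking contain no randomness at
all. Known limitations: no base-quality or damage-aware calling, no
heteroplasmy, per-position deletion tokens only (range deletions are
expanded on parse), and the QC recombination check is a deliberately
simple fragment-concordance rule (per-fragment best assignments whose
MRCA is near the root while the joint assignment is deep), not a full
rule-based QC system.
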