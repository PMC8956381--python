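# mitotrack

Haplogroup classification and iterative tracking for fragmented
mitochondrial DNA.

Typing the maternal lineage of degraded samples — ancient DNA above all —
rarely starts from a complete mitochondrial genome. What a laboratory
actually has is a handful of short PCR fragments, usually from the control
region (CR, positions 16024–576 across the replication origin), and the
question is not only *which haplogroup do these fragments support* but
also *which additional amplicons would settle the call*. `mitotrack`
answers both: it classifies multi-fragment samples against a
Phylotree-style haplogroup tree and then proposes, track by track, the
minimum set of coding-region amplicons that discriminates between the
surviving candidates.

## The method

**Variant calling.** Fragments are aligned to the rCRS coordinate system
with an affine-gap global aligner (Gotoh / Needleman–Wunsch; gap of length
*L* costs *open* + (*L*−1)·*extend*), run semi-globally so reference
overhangs are free, with circular-origin handling via a doubled reference.
Alignments become Phylotree-notation variants: transitions as bare
positions (`263`), transversions with the derived base (`16318T`),
insertions as `573.1C`, deletions as `249d`, back mutations with `!`;
indels are right-shifted to their 3′-most placement and hotspot positions
are masked.

**Ranking.** For a sample with *Vs* variants covering ranges *R*, each
haplogroup *g* is scored by its variant identity

    identity(g) = (Vp − Vm) / Vs

where *Vp* counts profile variants of *g* present in the sample and *Vm*
counts profile variants absent from the sample **within *R*** — a profile
variant the fragments never covered is not evidence against *g*.
Haplogroups sharing the four highest distinct identity values form Rank
Groups 1–4. Within a rank group, candidates are ordered by the
haplotype-frequency score

    score(g) = Σ_extras He(g,v)/H(g) + Σ_missing Hm(g,v)/H(g)

computed from a haplotype database built by iterative self-classification
of a sequence corpus: *H(g)* assignments of *g*, of which *He(g,v)*
carried the extra variant *v* and *Hm(g,v)* lacked the profile variant
*v*. Recurrent private variants thereby rescue assignments that identity
alone leaves tied.

**Tracking.** When Rank Group 1 holds several haplogroups, the tracker
narrows to the scored candidates (top five), finds their discriminating
variants on the tree, and greedily picks the amplicons that split the
candidate set into the most classes. New fragments are folded into the
profile and the sample re-classified; the loop ends when one haplogroup
remains, or when an unsplittable ancestor–descendant chain is reported at
its deepest member. An in-silico mode replays the loop on any haplogroup's
reconstructed reference sequence to count the amplicons a laboratory would
need.

The package ships a deterministic *synthetic* 16,569 bp stand-in for the
rCRS (same length, `N` at 3107, rCRS-like landmarks); all loaders accept a
real rCRS FASTA and a real Phylotree export (3-column TSV: haplogroup,
parent, variants) when available.

## Worked example

Generate a 20-haplogroup synthetic tree (with one CR-ambiguous sibling
pair), build the haplotype database from its corpus, and classify a
CR-only sample drawn from haplogroup `A2`:

```
$ mitotrack synth --seed 42 --n-haplogroups 20 --cr-ambiguous-pairs 1 --out synth
synthetic tree with 20 nodes -> synth
$ mitotrack build-db --corpus synth/corpus.fasta --tree synth/tree.tsv --out db
built DB over 74 records -> db
$ mitotrack classify --fragments sampleX.fasta --tree synth/tree.tsv --db db --out out
classified 1 sample(s) -> out
$ head -4 out/sampleX.classification.tsv
haplogroup  rank_group  Vp  Vm  Vs  identity  score  H   extras  missing
A           1           1   0   1   1.0       0.0    27
A3          1           1   0   1   1.0       0.0    24
A2          1           1   0   1   1.0       0.0    18
```

The CR fragments carry only `A`'s control-region variant, so `A` and its
siblings `A2`/`A3` (which differ only at coding positions 4849/9961) tie
at identity 1.0 in Rank Group 1 — exactly the ambiguity CR-only typing
produces. The tracker names the amplicons that resolve it:

```
$ mitotrack track --fragments sampleX.fasta --tree synth/tree.tsv --db db --out out
sampleX: candidates=['A', 'A3', 'A2'] -> out/sampleX.tracking.json
   "proposed_amplicons": [
     {"name": "amp012", "start": 4537, "end": 4936, "resolves": ["4849"]},
     {"name": "amp026", "start": 9577, "end": 9976, "resolves": ["9961"]}]
```

Sequencing those two amplicons and re-running finishes the track with the
true haplogroup. The in-silico simulation does this for every haplogroup
at once:

```
$ mitotrack simulate --tree synth/tree.tsv --db db --all-hgs --out sim.tsv
simulated 19 haplogroups -> sim.tsv
$ head -4 sim.tsv
haplogroup  final_hg  tracks  amplicons  agreed  stalled
A           A         2       6          True    False
A1          A1        1       4          True    False
A1a         A1a       1       4          True    False
```

`tracks` is the number of classify–propose–sequence cycles and
`amplicons` the total amplicons consumed (the four CR amplicons plus any
proposed coding ones); `agreed` records whether the final call matches the
simulated truth.

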