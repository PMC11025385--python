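# Methods

This note documents the models and procedures implemented in gh99kit, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Coordinate system and reference

All motif positions are 1-based residue numbers on the human MANEA protein
(UniProt Q5SRI9). Catalytic-domain numbering is related to full-length
numbering by a constant offset of 97 (domain 92 ↔ full 189);
`align.shift_numbering` converts in both directions and refuses results
below 1.

The packaged reference (`data/manea_reference_synthetic.fasta`) is a
synthetic 462-residue stand-in: a random background-composition sequence
carrying the canonical motif residues (Y189, DENGE at 195–199, HIEPY at
222–226, Y323, EWHE at 404–407) at the canonical coordinates. It defines
the coordinate system for every reference-anchored operation; users
analysing real data should substitute the real MANEA sequence via the
`--reference` option or the `reference` argument, which changes nothing
else in the machinery.

Within the −2 loop the package fixes D=195, [E/D]=196, N=197, G=198, E=199.
This is the only assignment consistent with the N197H variant being the
third loop residue, and it is used everywhere (extraction, annotation,
planting).

## Pairwise alignment and reference maps

`global_align` is a global (Needleman–Wunsch) alignment with affine gaps:
a gap of length *k* costs `gap_open + k·gap_extend`, end gaps included.
Defaults are BLOSUM62 with open 11 / extend 1 — the conventional protein
defaults. The engine is biopython's `PairwiseAligner` (configured with
`open_gap_score = −(open+extend)` so the cost model above holds exactly);
among co-optimal alignments the aligner's first traceback is returned,
which makes results deterministic. Correctness is cross-checked in the test
suite against exhaustive enumeration of all gapped alignments on short
sequences.

Two identity definitions are exposed and used consistently:

- **aligned-columns identity** (matches / alignment length) — used for
  phylogenetic distances (`d = 1 − identity`);
- **shorter-length identity** (matches / length of the shorter sequence) —
  used for clustering, matching cd-hit's semantics.

`build_reference_map` keeps exactly the match/mismatch columns of the
global alignment as a bidirectional, strictly increasing position map; gap
columns are unmapped. A query whose shorter-length identity falls below the
`identity_floor` (default 0.15) is reported as unmappable (`None`), not an
error: downstream annotation then returns fully undetermined fields with a
warning. The floor is deliberately permissive — at desk scale false
negatives (refusing to map a genuine homolog) are costlier than mapping a
weak one, whose motif calls will mostly be `?` anyway.

Alignments are not trimmed before distance computation; distances come from
untrimmed pairwise alignments. This is a deliberate simplification of
common practice (trimming matters most for deep-divergence multiple
alignments, which this package does not build).

## Motifs, logos, consensus

Motif spans are fixed constants (189; 195–199; 222–226; 323; 404–407).
`extract_motifs` is total: unmapped positions yield `?`, so partial
sequences never fail, they produce undetermined calls that downstream
percentage denominators exclude.

Position frequency matrices count the 20 standard residues; gaps and
unknowns are tracked separately and never enter the frequencies.
Information content per column is `IC = log2(20) − H` (bits), with H the
Shannon entropy of the column frequencies; no small-sample correction is
applied, and a column with zero observations has undefined IC (NaN), not
zero. Logo letter heights are frequency × IC.

Columns for logos, consensi and profiles come from **reference-anchored
stacking**: each sequence is pairwise-mapped onto the reference and its
residue is read at each reference position. No multiple alignment is
inferred; insertions relative to the reference are invisible to the column
stack. This is the package's explicit definition of "aligned columns".

Threshold consensus (`t ∈ (0.5, 1]`, defaults 0.90/0.95 as in standard
identity-consensus reporting): per column the modal residue is emitted when
its frequency over non-gap observations reaches `t`, else `X`;
majority-gap columns are dropped from the consensus and recorded. Because
`t > 0.5` the modal residue is unique whenever it passes the threshold.

## Annotation rules

The rule table, applied to extracted motif states:

- position 189: `Y` → glucose in −2 (endomannosidase-like, minimal
  substrate GlcMan3); `W` → mannose (endomannanase-like, Man4); any other
  mapped residue → `other_residue`; `?` → undetermined.
- positions 404/407: both `E` → predicted active; a mapped non-glutamate at
  either → predicted inactive (a mapped E404Q is decisive even when 407 is
  missing); otherwise undetermined.
- the 404–407 string is classified against {EWHE, EWGE, DYGE, KWHE}, else
  `other`. **DYGE is an exception**: it is the candidate active-site motif
  of the related GH71 family and also occurs in some GH99 proteins, but has
  no direct activity evidence, so its catalytic status is reported as
  undetermined rather than inactive.
- N197H is flagged (`present`/`absent`/`undetermined`) and never overrides
  the 189 or 404–407 calls; position 189 decides substrate preference
  regardless of loop content.

## Ohnolog profiles

For each of MANEA / MANEAL / CMANEAL a catalytic-domain profile is built
from seed sequences: reference-anchored columns over full-length positions
98 onward, scored as base-2 log-odds

    s(a, j) = log2( ((c_aj + α·q_a) / (n_j + α)) / q_a )

with pseudocount α = 0.5 and Robinson–Robinson-style background
frequencies q. Columns with no observations score 0 for every letter, as
does `X` in a query at any position (background neutrality). Queries are
scored by optimal global profile-to-sequence alignment under the profile's
position scores and the same affine gap model (a vectorised Gotoh
recursion, validated in the tests against the pairwise aligner on profiles
built from a single sequence).

Classification takes the best-scoring profile when its lead over the
runner-up reaches the decision margin δ (default 2 bits), else
`unclassified`; the full pairwise score-difference table is retained, since
plotting score differences is what separates the three ohnolog clusters.
Bit-score differences are used rather than E-values: they carry the same
clustering signal and are fully specified without a database-size model.
Ancestral single-copy (non-gnathostome) sequences are expected to fall in
the MANEA cluster; no fourth class is added. Raising δ can only turn a
label into `unclassified`, never change it — a property the tests assert.

## Clustering

`greedy_cluster` reimplements the cited cd-hit semantics
(`-c 0.95 -s 0.5 -g 1`): records sorted by length descending (ties by id),
each record joins the best eligible existing cluster — highest
shorter-length identity ≥ c among representatives passing the length
cutoff — or founds a new one. Identity comes from full DP alignment rather
than cd-hit's short-word filter: the filter is an accelerator, not part of
the definition, and correctness wins at desk scale. The sort makes output
independent of input order; ties between equally good clusters break by
representative id.

## Phylogeny and decontamination

Trees are built by canonical neighbor joining (scikit-bio's
implementation; negative branch lengths clamped to zero), which is exact on
additive matrices — the tests verify topology-and-length recovery on all
15 labeled 5-taxon topologies and seeded random 6–8-taxon trees, with an
exhaustive least-squares topology search as an independent oracle. NJ
stands in for maximum-likelihood tree building: the decontamination rule
needs only topology at desk scale.

The contamination rule (the package's explicit operationalization, recorded
in report metadata): a leaf is flagged when its **smallest enclosing
clade** — defined rooting-free as the smallest edge-induced split side of
the unrooted tree containing the leaf with ≥ k leaves (default k = 3) —
has a strict-majority taxogroup different from the leaf's, the leaf's
taxogroup is a minority there, and the majority taxogroup also occurs on
the other side of the split (the leaf is *nested inside* the foreign group,
not merely sister to its whole clade). Within a round, a flag whose only
nestedness witnesses are themselves flagged is voided, weakest backing
first, so a contaminant's wrong label cannot convict its innocent
neighbours. Flagged leaves are removed, the tree rebuilt from the subset
distances, and rounds repeat until nothing is flagged (max 5). The
procedure is idempotent on the surviving set by construction.

Limitations: the rule sees only topology and labels. A contaminant that
attaches *sister to* its mislabeled group's clade is indistinguishable from
a correctly labelled early-branching member and is not flagged; conversely,
when two taxogroups interleave heavily at high divergence, occasional
false convictions of stem-position leaves can survive the witness pruning.
At the calibrated study conditions (≈5% within-group divergence, one
planted contaminant) detection is exact and false-positive-free across
seeds, which is what the acceptance script measures.

## Prevalence and composition reports

Presence/absence counts species once regardless of how many records or
clusters they have; only cluster representatives count as surviving
records, so clustering can only lower per-species hit counts (a property
the tests assert). Clades whose searched-species universe is unknown are
flagged rather than given a fraction. Residue-composition percentages are
rounded to one decimal and computed over determined calls only; `?` calls
(partial sequences) are reported separately and excluded from denominators.

## Synthetic cohorts

The generator evolves the reference along simple lineages: each subfamily
gets its own ancestor (per-site substitution probability
`ancestor_divergence`, default 0.3, from the shared root — a realistic
inter-paralog distance), and members evolve from it through `depth`
independent steps (default 1, a star phylogeny) at per-site probability
`p`. Substitutions draw uniformly from the 19 alternative residues — the
simplest defensible choice absent a generative model. Indels are off, so
reference coordinates stay exact and planted motif states (written onto
positions 189, 197, 404–407 *after* evolution) are guaranteed recoverable.
Contaminants are generated inside their true subfamily and labelled with a
wrong taxogroup. Identical seeds give byte-identical records and truth.

What the generator does **not** emulate: site-rate heterogeneity,
realistic exchange matrices, indels (hence no coordinate drift), shared
within-subfamily tree structure, fragmentary transcripts, or annotation
noise. Passing recovery tests on these cohorts therefore demonstrates the
correctness of the machinery under its own model — that motif reading,
rule application, profile scoring, clustering and flagging do exactly what
they claim — not robustness to every artefact of real survey data.

## Problem sizes and numerical choices

The validation experiments use cohorts of 600 records (annotation
recovery), 3 × 112 records (ohnolog classification: 12 seeds + 100 queries
per subfamily at p = 0.15, δ = 2 bits), 12-leaf trees (decontamination,
replicated ten times), 20 records in 4 families (clustering), 30 sampled
short pairs (alignment oracle) and 60 random additive matrices (NJ
oracle) — sizes at which the exhaustive oracles remain exact and the whole
suite runs in well under a minute. Tolerances: alignment and NJ checks are
exact (float equality via `allclose` at 1e-9 for branch-length sums);
recovery rates are exact percentages; the ohnolog accuracy bound is ≥ 95%.
Ties are broken deterministically throughout (alphabetical modal residue,
representative id, first traceback), so every pipeline output is
reproducible byte-for-byte from a seed.
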