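# Methods

This note records the models behind each stage, the parameters that matter,
the conventions chosen where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open intervals; GFF3 output is
1-based inclusive, and the two conversions compose to the identity. FASTA
is canonicalised to uppercase over {A,C,G,T,N}; characters outside the
alphabet are an error in strict mode and are mapped to N otherwise. Newick
IO goes through Bio.Phylo; numeric internal-node labels are read as
bootstrap supports. Every stage logs a hash of its run configuration and
its input digests, so a serialised `RunConfig` plus inputs fully determines
a run.

## Structural detection of complete elements

A complete TRIM copy is a pair of co-oriented direct repeats (the LTRs)
within an element-size window. The scan:

1. **Seeding.** Exact shared k-mers (k = 15; windows containing N are
   unmatchable) at two positions on the same scaffold whose separation D
   (= LTR length + internal length) lies in
   [min_ltr + min_internal, max_element − min_ltr].
2. **Diagonal extension.** Seeds with equal D are clustered and extended
   along the diagonal with an x-drop rule (drop 20) under +2/−3 scoring.
3. **Boundary refinement.** Both edges are searched within ±10 bp for the
   placement maximising column score plus a bonus of 8 per terminus pair
   conforming to TG…CA and 14 for identical flanking 4-mers. The TSD bonus
   deliberately exceeds a single terminus bonus: the TSD is an exact
   host-sequence duplication and pins the boundary even when a terminal TG
   or CA has mutated, whereas a shifted placement can satisfy TG/CA by
   chance (the LTR consensus ends …CACA, so a −2 bp shift often still shows
   CA). Candidates failing termini at both ends are kept but flagged
   (`termini_ok`), never silently dropped.
4. **TSD call.** A 4-bp TSD is called iff the 4-mers immediately flanking
   the element are identical (exact 4/4; the duplication is exact biology,
   and exactness keeps downstream TSD statistics unambiguous).
5. **Conflict resolution.** Overlapping candidates keep the higher score;
   output is deterministic and invariant to scaffold order.

Defaults: LTR length 100–350 bp (hard floor 50), internal region 50–700 bp,
element ≤ 1000 bp, minimum LTR identity 0.80. These are the family's
canonical dimensions; the floors mirror the scan settings appropriate for
miniature elements.

**PBS**: the longest match (≥ 10 bp, ≤ 1 mismatch) between the first 25 bp
of the internal region and the reverse complement of any supplied tRNA 3'
end; ties prefer exact matches, then the earliest start, then tRNA input
order. **PPT**: the most 3'-proximal 15-bp window with purine fraction
≥ 0.8 within the last 30 bp of the internal region.

## Solo-LTR and truncated recovery

Representative LTRs (and the full sequences of detected complete elements)
are aligned against both strands with Smith–Waterman (+2/−3 match/mismatch,
−5/−2 affine gaps), restricted to candidate windows that share an exact
12-mer with the query — a linear-time prefilter that leaves the alignment
itself unchanged. Library entries are first deduplicated at 90% identity
(family copies are near-identical; this mirrors consensus-library
practice). Local alignment trims mismatching termini, so up to 5
unconsumed query bases at each end are restored by positional
correspondence — exact whenever the copy differs from the library by
substitutions only.

Overlapping hits merge into one region. Regions inside a complete
candidate are absorbed into it. A region is a **solo-LTR** when a library
LTR is covered to ≥ 0.80 and the region does not extend materially past one
LTR length (≤ 1.25×); its boundaries come from the best LTR-library hit,
which the TSD flanks anchor exactly. Anything else — a fragment of an
element, or partial LTR coverage — is **truncated**, with boundaries from
its best (usually full-element) hit.

**A limitation stated plainly:** the cut end of a truncated fragment has no
anchor. A background base that happens to match the next library position
(probability ≈ 0.26 per column) is indistinguishable from fragment
sequence, so local alignment overshoots the true cut by 1–8 bp on roughly a
third of truncated copies; no algorithm can resolve this. Validation
therefore scores complete and solo copies **coordinate-exact** and
truncated copies by correct category plus ≥ 95% reciprocal overlap.

## Insertion-age dating

Model: the two LTRs of an element are identical at integration and then
accumulate substitutions independently and neutrally, so their divergence
measures twice the time since insertion. The pair is globally aligned
(match +1, mismatch −1, gap −2, end gaps penalised, traceback ties broken
diagonal → up → left for determinism); columns containing a gap or N are
excluded from the site count, matching the substitution-only model (indel
columns can be included via a switch, default off). The Kimura 2-parameter
distance is K = −½ ln[(1 − 2P − Q)√(1 − 2Q)], and T = K/(2r) in years.

`r` is a configuration constant, default 0.54 × 10⁻⁸ synonymous
substitutions/site/year (an average for ant nuclear genes); estimating `r`
is out of scope. Saturation (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) raises an error
rather than clamping — silently capped ages would corrupt age histograms.

## Spatial statistics

The randomization test draws, per replicate, n element positions uniformly
over the concatenated assembly — scaffolds weighted by length, the natural
reading of "a random position in the genome" — and counts distinct scaffolds
hit; p = (1 + #{null ≤ observed})/(reps + 1), the +1 correction giving
finite-sample validity (p is never exactly 0). Default 5000 replicates.
Densities assign elements to regions by interval midpoint; clusters are
single-linkage merges of same-scaffold copies with gaps ≤ max_gap.

## Insertion-site profiling

Each copy with a called TSD and full flanks contributes a 14-mer context:
5 bp upstream flank, the 4-bp TSD, 5 bp downstream flank (positions
−5…−1, T1…T4, +1…+5). From the position frequency table: GC content of a
position subset is (C+G)/(n·|subset|); modal nucleotides are per-position
maxima as percent of n; logo information content is R = 2 − H bits with
H the column Shannon entropy, optionally minus the small-sample correction
e(n) = 3/(2 ln2 · n) (default off, since reference logo tools differ);
letter heights for rendering are p·R. Rendering uses matplotlib directly.

## Element phylogenetics

TN93 distances use per-pair empirical base frequencies under pairwise
deletion (gap/N columns dropped per pair) — the default, since each pair's
comparable sites are its own evidence; `freq_mode="alignment"` pools
frequencies across the alignment, matching the convention of common
distance programs (verified against R `ape::dist.dna` to < 1e−9).
Saturated pairs raise an error naming the pair.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties are broken by the lexicographically smallest pair of
cluster labels, and negative branch lengths are clamped to zero with the
deficit logged. Bootstrap resamples alignment columns with replacement and
reports bipartition frequencies (%) on the full-data tree.

Subfamilies are cut from the tree as maximal splits: both sides of every
internal edge with support ≥ min_support are candidates, provided mean
within-group patristic distance ≤ max_within; maximal disjoint candidates
are selected largest-first, and leaves outside every candidate stay
`unassigned` (both sides of an edge are considered because the NJ root is
arbitrary and a genuine cluster can sit astride it).

Multiple alignment construction is plumbing: the module accepts pre-aligned
FASTA and ships a simple center-star progressive aligner for synthetic
tests; reproducing any specific alignment program is a non-goal.

## Host-level parsimony

The presence/absence of the element family across hosts is analysed on a
rooted binary tree with Fitch parsimony (unit-cost Sankoff tables). All
most-parsimonious reconstructions are enumerated by backtracking; per MPR,
gains are absent→present edges and losses the reverse (the root's own state
is not a change). ACCTRAN and DELTRAN are selected from the enumerated MPR
set: ACCTRAN minimises the summed root-distance of change edges (changes
as close to the root as possible), breaking ties by fewest gains (it
favours reversals); DELTRAN maximises the summed root-distance, breaking
ties by most gains (it favours parallel gains). Polytomies are rejected —
resolve them upstream.

The packaged host fixture is a 13-taxon tree (12 ant species, *Apis
mellifera* outgroup) with genus relationships following published ant
phylogenies. The within-Myrmicinae resolution of the source figure is
partly ambiguous; the packaged topology places Pogonomyrmex basal within
the sampled Myrmicinae, Aphaenogaster+Messor as a clade, and Pheidole
sister to Solenopsis inside the Crematogaster clade. Under this topology
the presence/absence character needs 4 steps with exactly 3 MPRs (4 gains;
2 gains + 2 losses; 1 gain + 3 losses); alternative placements of
Crematogaster/Solenopsis yield 1 or 5 MPRs, so the reconstruction pattern
itself disambiguates the figure.

## Synthetic genomes and what validation shows

The generator emulates the study conditions: background scaffolds at
genome GC 0.37; optional AT-rich hotspot blocks at GC 0.19 (the observed
flank composition) with registry-recorded positions; planted complete
elements (LTR + internal + LTR, TG…CA termini, PBS/PPT in the internal
template, total < 1000 bp), solo-LTRs and truncated copies; insertion
duplicates the 4-mer already at the target site on both sides of the copy
(net growth = element + 4 bp), so planted TSDs are host-derived as in real
integrase biology; truncated copies are inserted bare, since a real
end-truncated copy has lost at least one TSD flank. LTR pairs are diverged
by a K2P substitution process calibrated so the expected pairwise distance
equals 2·r·age; the instantaneous ts:tv ratio defaults to 2 — a free
parameter chosen so both P and Q are exercised — and requested divergences
≥ 0.7 are rejected as unusable for dating. Indels are available as an
option but excluded from site counts by default, matching the
substitution-based clock. `simulate_homolog_set` evolves a family along a
host tree and implements horizontal transfer by copying the donor sequence
into the recipient at a small residual divergence (default 0.01).

Validation on these genomes shows that the pipeline recovers what was
planted under the stated model: substitution-driven divergence,
independent copies, uniform or block-structured composition. Real genomes
add features the generator does not emulate — nested insertions, segmental
duplications, indel-rich decay, compositional heterogeneity beyond
two-state GC, assembly gaps and collapsed repeats — so passing tests bound
algorithmic correctness, not real-data annotation completeness.

Validation problem sizes (chosen to exercise the statistics at meaningful
power): detector recall/precision on a 16-scaffold ≈ 400-kb genome with 36
planted copies across all categories and ages 0–8 My; randomization
calibration over 200 simulated uniform genomes (400 replicates each) with
binomial 99% bounds on the type-I rate, and power on a genome with copies
confined to 10% of scaffolds; age recovery with 120-element cohorts at
0.5, 2, 5 and 10 My (300 comparable sites each); NJ consistency on 100
random additive 8-taxon matrices; horizontal-transfer bootstrap on a
5-species tree with 600-bp elements and 500 replicates.

## Known limitations

* Truncated-fragment boundary fuzz (above): 1–8 bp overshoot at cut ends is
  irreducible; downstream statistics use midpoints and are insensitive.
* The detector targets direct (co-oriented) LTR pairs on one strand;
  inverted repeat pairs and nested elements are out of scope.
* Family grouping applies the 80/80 rule with semi-global alignments;
  highly fragmented copies may fall below coverage and stay unassigned.
* The parsimony engine is binary-character, rooted-binary-tree only, by
  design; multistate characters and polytomies are not supported.
* ACCTRAN/DELTRAN are defined via the depth-of-change criterion described
  above; programs using node-by-node uppass conventions can differ on trees
  with multiple equally root-near MPRs, though both tracings are always
  members of the enumerated MPR set here.
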