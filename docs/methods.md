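# Methods

## Coordinate system and site naming

All analysis runs in CDS coordinates: 1-based nucleotide positions within
the spliced coding sequence, 5′→3′ in transcript orientation. A site named
`nad7-77` is the 77th CDS nucleotide of *nad7*; its residue number is
`ceil(77/3) = 26` with codon offset `((77−1) mod 3)+1 = 2`. Genomic
intervals are 1-based and closed. Gene models come from GFF3 CDS features
grouped by `Parent`; for minus-strand genes the coordinate map runs
descending genomic → ascending CDS, and CDS extraction reverse-complements
each segment before concatenating in transcript order. The maps are exact
bijections between CDS indices and the union of CDS segments (verified
exhaustively in tests). Spliced genes are handled through the concatenated
CDS; editing sites in intronic pre-mRNA are out of scope. A CDS length that
is not a multiple of 3 warns rather than fails, because organellar
annotations can be ragged.

## Editing extent and site discovery

The extent of a site in a library is `n_T/(n_T + n_C)`; reads carrying any
other base are tracked separately and excluded from the denominator. Zero
informative coverage yields NA, never a silent 0. Tallies are taken directly
from aligned reads (pysam), counting only aligned match positions with base
quality ≥ 20 by default; duplicate reads are counted, since deduplicating
amplicon libraries would distort extents. On minus-strand genes the genomic
pileup bases G/A are complemented into CDS-orientation C/T.

Pooling across the two WT libraries sums counts before dividing
(`Σn_T/(Σn_T+Σn_C)`), weighting libraries by depth; a per-library mean is
available but not the default. Site discovery uses three thresholds with
defaults chosen as ordinary practice for deep amplicon data rather than
taken from any reference analysis: pooled WT depth ≥ 50, extent ≥ 5% in at
least one WT library, pooled other-base fraction ≤ 5%. All are exposed on
the API and CLI.

Extent bins for editotype reporting are `=1.0`, `[0.99, 1.0)`,
`[0.90, 0.99)`, `[0.50, 0.90)` and `[0, 0.50)` — a fixed closed-open scheme,
with "100%" meaning exactly 1.0 after pooling, stated here because verbal
bin labels are ambiguous at the edges.

## The differential rule

With libraries WT-1, WT-2, mut-1, mut-2, the four pairwise deltas are
`100·(extent_mut_i − extent_wt_j)` in percentage points. A site is
*decreased* iff all four deltas are ≤ −10, *increased* iff all four are
≥ +10; the threshold is a parameter (default 10 points). *Abolished* means
the decreased criteria plus no detectable mutant editing: pooled mutant
`n_T ≤ 0` **or** pooled mutant extent ≤ 0.005. The OR-form tolerance exists
because at high depth with a nonzero sequencing error rate a truly
unedited site still collects a handful of T reads; 0.5% is well below any
biologically meaningful residual extent yet above the error floor at the
depths this design uses. Any library with informative depth
(`n_C + n_T`) below 20 makes the site *not evaluable*; such sites are
excluded from summary denominators and listed separately instead of being
classified from noise.

The rule is deterministic — no statistical test decides the label. A
per-pair Fisher exact test is available for annotation only. Threshold
comparisons use an absolute tolerance of 1e-9 points so that count ratios
landing exactly on the threshold (e.g. 40% vs 50% at depth 1000) stay
inside the rule despite float rounding.

Labels are invariant under swapping the two WT or the two mutant libraries
(pairing is by sorted library id), and monotone in the mutant edited-read
count: raising mutant n_T at fixed depth can never move a site from
increased toward decreased. Both properties are tested.

## Codon consequences

For each codon carrying k editing sites, all 2^k combinations of per-site
edit status are enumerated, keyed by bit tuples in ascending CDS position,
and translated with NCBI genetic code table 1 (plant mitochondria use the
standard code; the table id is configurable). The all-unedited outcome
always equals the translation of the genomic codon. The primary recoding
class compares the all-unedited and all-edited outcomes with priority
stop_gain > stop_loss > start_gain > missense > silent; start_gain applies
only when codon 1 becomes ATG. "Edited" in per-site reports means all
sites in the codon edited; partial combinations live in the `CodonEffect`
detail. Consistency across granularities (translating the fully edited CDS
equals composing per-codon fully-edited outcomes) is tested.

## PPR-code matching

A PLS array of k nucleotide-binding motifs (E1/E2/DYW excluded) is aligned
to the window −(k+3)…−4 upstream of the candidate C (position 0), the
C-terminal-most motif pairing with −4 — for the common 11-motif array this
is the −14…−4 window. Motif *i* (N→C) therefore reads window position
−(4+k−i). Each motif's prediction comes from the combinatorial (6, 1′)
code table: *match* when the window nucleotide is the top-weight
prediction, *partial* when a lower-weight one, *no_prediction* when the
pair is absent, else *mismatch*. The score is
`(matches + 0.5·partials) / predicted positions` (0 when nothing is
predicted). The 1/0.5 weights and the normalisation are this package's own
design — published analyses report such alignments qualitatively — and are
parameterised. A motif-type mask can exclude L motifs, which some published
codes leave out; the default uses all array motifs. Ranking is by
descending score with deterministic (gene, position) tie-break.

The shipped `ppr_code.yaml` transcribes the well-supported pair
preferences (TD→G, TN/SN→A, ND→U, NS/NN→C, …) with approximate weights;
it is a versioned, user-replaceable asset, and all tests run on toy tables
so no conclusion depends on the shipped weights.

## Synthetic data generator

The generator emulates the amplicon editing-survey design end to end:

- **Genome**: ~35 genes (maize mitochondrial names and categories by
  default) on one contig, strands alternating, roughly every fifth gene
  split into two CDS segments, CDS lengths uniform in 300–1500 nt (forced
  to triplets), ATG start and TAA stop. Planted sites are placed ≥ 18 nt
  into the CDS (keeping PPR windows extractable) and their base set to C;
  codon context is otherwise random, which yields a natural mix of
  recoding classes.
- **WT extents** follow the empirical editotype mixture: point mass at 1.0
  and four bin components with masses 12/72/170/154/85 over 493, uniform
  within each bin interval. Uniform-within-bin is a deliberate, simple
  choice; only the bin masses carry the empirical signal.
- **Effect classes** are planted in proportions 5/76/22/390 (abolished /
  decreased / increased / unaffected), scaled by largest remainder for
  other site counts. Effect magnitudes are ≥ effect_min = 0.20 (the
  10-point threshold plus a 10-point margin) and ≤ 0.60. Feasibility
  constraints follow from the rule itself: abolished sites need WT extent
  ≥ 0.15, decreased sites keep a residual mutant extent ≥ 0.05 (so they
  are never mistaken for abolished), increased sites need WT ≤ 0.80.
  Labels are assigned by seeded draws from the feasible pools, most
  constrained first.
- **Counts**: per site and library, depth d ~ Poisson(2000 by default);
  (n_T, n_other, n_C) are one multinomial draw with cell probabilities
  `p_T = e(1−ε) + (1−e)ε`, `p_other = ε/2`, remainder — so marginally
  n_T ~ Binomial(d, p_T) and n_other ~ Binomial(d, ε/2) while depth is
  conserved exactly. ε defaults to 0.001.
- **Reads**: 150 nt reads tiling each gene at the configured coverage;
  each read's edit status is drawn independently per overlapped site, and
  the simulate-time tally is returned so `tally_site_counts` on the SAM
  output can be checked for exact equality. Sites within a read are
  independent (no editing linkage) — a stated simplification.

What passing tests on this generator shows: that the tally, extent, rule
and consequence machinery is exact and recovers planted truth under the
stated noise model. What it does not show: robustness to misalignment,
indels, PCR chimeras, quality-dependent error profiles, editing linkage
within molecules, or uneven amplicon coverage — none of which the
generator emulates.

Persisting fixtures without a seed is refused; same-seed runs are
byte-identical.

## Problem sizes and determinism

The default fidelity checks run a 493-site, 4-library simulation at mean
depth 5000 (clean, exact composition recovery) and depth 1000 with
ε = 0.001 (≥ 99% per-site label recovery) — both complete in seconds on
one CPU. Count-level simulation is used wherever read-level detail is not
the point; read-level round trips run on small genomes (4–5 genes, depth
≈ 100). All randomness flows through explicit numpy Generators; pipeline
outputs are sorted by (gene, position) and hashed into a manifest, so a
rerun with identical inputs is byte-identical.

## Known limitations

- Only C→U editing on CDS positions is modelled; U-to-C editing and
  non-coding/intronic sites are out of scope.
- The 2 WT + 2 mutant design is the tested configuration; other designs
  require generalising the pairwise rule.
- Real-genome use requires the user to supply a matching FASTA + GFF3 pair;
  no coordinate lifting between assemblies is provided.
- The PPR scorer ranks candidates; it does not claim binding predictions —
  with real motif residues its output should be read qualitatively, as a
  relative alignment ranking.
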