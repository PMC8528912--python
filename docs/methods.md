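# Methods

`ogripan` re-implements, as one tested pipeline, the genome-based workflow
used to revise the taxonomy of a bacterial class from whole-genome data:
pairwise overall genome relatedness indices (OGRIs), threshold-based
delimitation of genus/species/subspecies ranks, orthology-based pangenome
partitioning with openness metrics, gene-dose phyletic patterns and
gene-vicinity concurrence networks, and concatenated single-copy-marker
distance phylogenomics.  Every stage can be exercised end-to-end on a
bundled synthetic clade simulator with exact ground truth, so the
package's correctness claims rest on recovery experiments rather than on
re-downloading public assemblies.

## Synthetic clade simulator (`synthetic_clade`)

**Model.** A rooted binary tree with branch lengths in expected
substitutions/site drives a Jukes–Cantor substitution-only process.  Each
site mutates with probability p(t) = (3/4)(1 − e^(−4t/3)) per branch,
uniformly to one of the three alternative bases — the exact JC transition
kernel, so successive branches compose additively and the closed form
`expected_identity(d)` is exact for any path length.  There are no
indels: per-family alignments are positionally trivial, which removes
multiple sequence alignment from the test loop (alignment of real data is
an input, not a step, of this package).

**Genomes.** The ancestor carries `n_genes` (default 200) protein-coding
genes of ~`gene_len_mean` codons (default 300, drawn uniformly ±25%),
each built as ATG + stop-free codons + TAA at the target G+C (default
0.55), on one contig with `intergenic_len` = 120 bp spacers, random
strand.  During evolution the terminal stop codon is frozen and any
substitution that would create an internal stop is redirected to a
non-stop alternative; the site still changes, so the expected proportion
of differing sites is preserved (residual bias ≪ the tolerances used
anywhere).  Spacers evolve unconstrained.  Proteins are the table-11
translations of the CDS.

**Gene content.** Per branch of length t, each gene is lost with
probability 1 − e^(−loss_rate·t); surviving genes duplicate in tandem
with probability 1 − e^(−dup_rate·t); Poisson(gain_rate·t·n_genes) gain
events insert novel random genes (optionally 3-gene cassettes via
`gain_cassette_size`), founding lineage-exclusive families.  Tandem
duplicates evolve concertedly: same-genome copies of a family are
homogenized at the end of every branch (complete gene conversion, the
limiting form of the concerted evolution seen in tandem arrays shaped by
unequal crossing-over).  The consequence matters for testing: simulated
in-paralogs stay near-identical, so the 60% ortholog/paralog
discrimination threshold of the clustering stage assigns them cleanly to
their family of origin and descent-based truth and identity-based
clustering can agree exactly.  Without concerted evolution, copies of
ancient duplications drift below any fixed identity threshold and the
two family definitions must eventually diverge — which is also true of
real data, and why the dose matrix of deeply diverged paralog families
is method-dependent there.  Default
rates (gain 0.15, loss 0.10, dup 0.05 per gene per unit branch length)
yield, on the default tree, a mostly-core pangenome with a visible
flexible/exclusive fringe and occasional copy-number variation —  the
qualitative structure of a within-class bacterial pangenome.  Every event
is logged; `replay_event_log` replays the log independently of the
emitted sequences and must reproduce the per-genome family doses exactly.

**Truth object.** The generating tree, the additive pairwise divergence
matrix, the family history (dose per genome), the event log, and lineage
labels.  Lineage labels are obtained by single-linkage cutting of the
pairwise path distances at configurable cutoffs (genus 0.25, species 0.05
substitutions/site) — equivalent to cutting the tree at depth thresholds
for near-ultrametric trees, and well defined for any tree.

**Default study tree.** 12 genomes = 3 genera × 2 species × 2 strains;
strain branches 0.005, species stems 0.045, genus stems 0.125/0.175 with
a 0.05 root edge.  The resulting index values fall clearly on the correct
sides of all decision thresholds: within-species ANI ≈ 99 (> 95.9),
between-species ANI ≈ 90.6 (< 95.9), within-genus AAI ≈ 75–80 (> 70),
between-genus AAI ≈ 50–55 (< 65), dDDH concordant with ANI, and 16S
identity separating genera (≈ 98.3 < 98.7) while — deliberately, as in
real data — lacking the resolution to split species within a genus
(≈ 99.5 > 98.7); the delimitation report surfaces that disagreement.

**What the simulator does not emulate.** Indel evolution, genome
rearrangement (gene order is conserved apart from gain/loss/duplication),
recombination/HGT between simulated lineages, codon-usage and
composition heterogeneity, multi-contig drafts, contamination, and
annotation error.  Passing recovery tests therefore demonstrates that the
statistics and algorithms are implemented correctly and are calibrated on
substitution-dominated divergence; they do not certify behavior on noisy
real assemblies.  The 16S-like marker is emitted as a separate locus per
genome rather than embedded in the assembly.

## Relatedness indices (`ogri`)

* **ANIb** — the query is cut into consecutive 1020 bp fragments
  (terminal shorter fragment kept, judged by coverage of its own length);
  each fragment's best local hit must reach ≥ 30% identity over ≥ 70%
  coverage to be retained; ANI is the mean retained identity, and the
  matrix stores the mean of the two directions.  Cells with no retained
  fragment are flagged NA, never 0.
* **TETRA / TZMD** — tetranucleotide counts over both strands of all
  contigs; the maximal-order Markov expectation
  E(w) = N₃(n₁n₂n₃)·N₃(n₂n₃n₄)/N₂(n₂n₃) with its variance gives z-scores
  (zero-variance words score 0, keeping the vector at 256 components);
  TETRA is the Pearson correlation of two z-vectors and TZMD their
  Manhattan distance, divided by 256 under the default "mean-per-word"
  normalization ("raw" is configurable — the original tool's constant is
  not published).
* **dDDH (formula 2)** — whole-genome HSPs from the internal aligner,
  d₂ = 1 − Σidentities/ΣHSP-length; d₂ is the tested quantity.  The
  percent estimate uses a logistic map ddh = 1/(1 + e^−(a + b·d₂)) with
  a = 2.149435, b = −24.452202 kept in configuration (the regression
  constants of the reference implementation are not printed in the
  source literature; d₂ = 0 maps to the transform's maximum, ≈ 89.6%).
* **AAI** — all-vs-all BLOSUM62 local alignments behind a two-rule
  candidate prefilter (shared 5-mers anywhere, or shared 3-mers
  concentrated on one alignment diagonal with a cheap ungapped screen —
  the second rule keeps ~30–40%-identity homologs visible); hits filtered at ≥ 30% identity over ≥ 70% of the
  shorter sequence; reciprocal best hits with deterministic tie-breaking
  (score, alignment length, self-hit preference, lexicographic id); AAI
  is the mean RBH identity.
* **16S identity** — global end-gap-free alignment; terminal overhangs
  excluded from the denominator.
* **G+C** — mol% over unambiguous bases, to 1 decimal.

**Internal DNA aligner.** k-mer-seeded (k = 11, both strands) diagonal
matching, ungapped extension by maximal-scoring-segment search (match +1,
mismatch −2; among co-optimal segments the shortest is taken, matching
the DP oracle's boundary convention), then banded gapped chaining of
co-linear HSPs with affine costs (open −5, extend −2 per column; band 50,
bridge ≤ 200).  Queries above 5 kb require ≥ 3 seeds per diagonal
(fragment-sized queries ≥ 2) to suppress noise diagonals.  A full
dynamic-programming local-affine mode serves as the independent oracle on
inputs of a few kb; on substitution-only pairs the heuristic must match
it exactly.  E-value cutoffs of BLAST-based workflows are represented by
minimum alignment scores (no database-size statistics); the configuration
documents the substitution.  ANIm (a maximal-exact-match backend) is not
implemented; ANIb alone carries the species decision.

## Rank delimitation (`delimitation`)

Thresholds (configurable): genus AAI > 70 with a documented [65, 72] gray
zone (pairs inside it are flagged "borderline"), species ANI > 95.9
cross-checked against dDDH > 70 and 16S > 98.7, subspecies dDDH > 79 —
the subspecies value is an explicit stand-in, the source analysis states
no numeric subspecies cutoff.  Single linkage (connected components of
the pass-threshold graph) is the default, with every within-cluster pair
failing the threshold recorded as a chaining conflict; complete linkage
(scipy hierarchical, cut at the threshold) is available because
near-threshold chaining is a known hazard.  ANI is authoritative for
species; dDDH/16S partitions that disagree produce report rows, never
silent overrides.  Species labels are intersected with genus labels (and
subspecies with species) so the three ranks always nest; any forced
refinement is logged.  Partitions are compared by the pair-counting
adjusted Rand index.

## Pangenome (`pangenome`)

Orthology follows the RBH-triangle ("COG triangles") idea: per-pair
reciprocal best hits (hits must cover ≥ 75% of the query and reach the
score floor), 3-genome RBH triangles, transitive merging of triangles
sharing an edge.  The 60% identity ortholog/paralog discrimination rule
is then applied in three places: genes in no triangle join the family of
their best ≥ 60%-identity hit; leftover mutually-best pairs at ≥ 60%
form two-member families (families carried by only two genomes cannot
form a triangle); and families whose same-genome members align at ≥ 60%
identity over ≥ 70% of the shorter sequence are merged
(`paralog_merge` — a lineage-wide duplication otherwise puts the second
copies into their own RBH cluster).  Remaining genes become singleton
families.  `paralog_split` finally re-examines multi-copy genomes:
same-genome copies under 60% identity to a cross-genome representative
are split out unless their ±2-gene neighborhood shares a family with the
other members' neighborhoods (an automated stand-in for manual
genomic-context curation; rescues are logged).

Compartments: **core** = present in ≥ `core_occupancy` (default 1.0) of
genomes; **exclusive** = confined to one species-level lineage;
**flexible** = the rest.  Copy-number-variable families are those
reaching dose ≥ 2 anywhere; the summary reports the fraction of genes in
them and the carrier dose range, plus the Pearson correlation of
per-lineage core size against lineage sample size when ≥ 3 lineages are
present.  Heaps openness is fitted the permutation way: new families
counted at each genome addition over `n_permutations` seeded
permutations, medians fitted by least squares on logs of
n(N) = κ·N^(−α) over N ≥ 2 with positive medians; α < 1 reads "open";
degenerate inputs (no new families beyond N = 1, or fewer than two
usable points) yield a flagged, undefined fit rather than a number.

## Context networks (`context_networks`)

Gene neighborhoods are windows of ± `window_k` genes (default 5) on the
same contig, strand ignored.  Concurrence frequency of a family pair =
100 × (genomes where members of both lie within the window of each
other) / (genomes carrying both); the all-genomes denominator is reported
alongside, because the source description of "% concurrence" is ambiguous
— both-carriers is the default.  No co-occurrence significance test is
attached (none is described for the original networks); raw frequency is
the only edge weight, exported as TSV, GraphML and SIF.  Phyletic
patterns are dose submatrices ordered by a guide tree's leaf order or a
rank table.

## Phylogenomics (`phylogenomics`)

Markers are families passing occupancy ≥ 1.0, ≤ 1 copy per genome,
member length within ±25% of the family median, and X/stop fraction
≤ 0.02 (a single filtering pass; the iterative accrual of the original
workflow gives no iteration schedule).  Markers concatenate in sorted
family-id order (partition map preserved); columns with gap fraction
> 0.5 are trimmed.  Distances are p (mismatches/overlap, pairwise gap
deletion) or Poisson-corrected −ln(1 − p); WAG-model distances are an
extension point, not implemented, to keep the core deterministic and
dependency-free — on synthetic data the Poisson correction suffices for
exact topology recovery.  Neighbor joining is the standard Saitou–Nei
Q-criterion with deterministic tie-breaking (lowest lexicographic pair)
and negative branch lengths clamped to zero with the deficit logged; on
any additive matrix it recovers the generating topology exactly (tested,
and cross-checked against an independent implementation).  Bootstrap
resamples columns with replacement, rebuilds the tree per replicate, and
reports the percentage of replicates containing each internal bipartition
of the point tree.  Robinson–Foulds distance is the symmetric difference
of non-trivial bipartitions.

## Problem sizes and numerical choices

Validation experiments run at sizes chosen to make each property
measurable with comfortable margins: the reference clade is 12 genomes of
~205 kb (200 genes × ~906 bp + spacers); divergence calibration uses
200-gene (~205 kb) pairs, where the binomial standard error of identity
at 95% is ≈ 0.05 percentage points against the ±0.5 tolerance; the
monotonicity experiment follows one evolutionary trajectory per seed
(snapshots of a single evolving genome, so divergence accumulates along
the path instead of being re-simulated independently) over the six-point
grid d ∈ {0.005, 0.012, 0.025, 0.05, 0.09, 0.15} — capped below
tetranucleotide-signature saturation (d ≳ 0.2), where the bounded TZMD
statistic plateaus and pathwise monotonicity is no longer an expected
property; bootstrap uses 200 replicates (supports on the reference clade
are saturated at ~100, so added replicates change nothing); the
open-pangenome experiment uses a 12-genome uniform tree with gain rate
2.0 over 300 ancestral families, large enough that the Heaps exponent is
estimated from hundreds of gain events and varies by ≲ 0.05 across
seeds.  Heaps permutations default to 100.

Degenerate inputs are flagged, not coerced: incomputable matrix cells are
NA in TSV exports and block downstream clustering with an explicit error;
Heaps fits without usable points are flagged; Poisson distances at p ≥ 1
and pairs with < 50 overlap columns are flagged.  All randomness flows
from a single integer seed per entry point (simulation, Heaps
permutations, bootstrap), and identical seeds give byte-identical
outputs.

## Known limitations

The aligner is a deliberately small BLAST-like engine: no E-values, no
X-drop gapped DP (gapped alignments come from HSP chaining), and gapped
identities count bridged columns as mismatches — adequate for the
substitution-dominated regime it is tested in, approximate for highly
indel-rich real pairs.  dDDH percent values depend on configurable
logistic constants and should be read as relative, not calibrated,
estimates; d₂ is the reliable quantity.  The COG-triangle recruitment
pass is single-step (no iterative re-recruitment).  Complete-linkage
clustering uses the hierarchical cut rather than clique merging.  16S
markers are simulated as separate loci; real multi-copy rRNA operons and
intragenomic 16S heterogeneity are out of scope.
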