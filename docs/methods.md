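# Methods

This note documents the statistical model behind each stage, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical design decisions.

## Coordinates and formats

Internally all intervals are 0-based half-open on the promoter or contig.
GFF3 input (1-based inclusive) and BED output (0-based half-open) are
converted at the parsing/writing boundary only. Promoter sequences are
always reported 5'→3' on the gene's strand, so "offset 0" is the distal end
and offset `L` abuts the start anchor.

## Promoter extraction

For a gene anchored at its start codon (default) or annotated TSS, the
promoter is the `l_prom` = 1,500 bp immediately upstream on the gene's
strand. A promoter is excluded when (a) it overlaps any *other* gene's CDS
by ≥ 1 bp (`cds_overlap`), (b) it is truncated below `min_length` by a
contig edge (`truncated_below_min`, default `min_length = l_prom`), or
(c) its contig is missing from the genome FASTA (`missing_sequence`).
Exclusions are reported per gene with their reason; the surviving set is
the "valid regulatory region" universe used by every downstream stage.

## Background model

A k-th-order Markov chain (default k = 3) over {A,C,G,T} estimated from
intergenic sequence on the forward strand only; scanning handles the other
strand by reverse-complementing the query window, never the model.
Transition rows are `(count + β) / (count(ctx·) + 4β)` with pseudocount
β = 1; contexts never span sequence boundaries or runs of N. Positions
without a full k-context (sequence starts, post-N positions) fall back
through successively shorter contexts ending at the pseudocounted
mononucleotide distribution. Order 3 balances realism (captures local
dinucleotide/trinucleotide composition typical of plant intergenic DNA)
against the 4⁴ = 256 transition rows that must be estimated; the builder
warns when the input has fewer than 4^(k+1) usable bases.

## Motif discovery (Gibbs site sampler)

The sampler follows the classical site-sampler scheme: hold one sequence
out, build the PWM from the remaining sequences' current sites with
background-proportional pseudocounts (γ = 1 total, split by the background
stationary distribution), and resample the held-out sequence's site
proportionally to the PWM/background likelihood ratio over all windows.
One site per sequence during core sampling; the best-scoring state over
all sweeps is kept, not the last. After convergence, up to
`max_sites_per_seq` − 1 = 2 extra sites per sequence are added greedily
(non-overlapping) where the likelihood ratio exceeds the weakest sampled
site's ratio, honouring the "up to three sites per sequence" contract.

Per run, up to `n_motifs_per_run` = 6 motifs are extracted sequentially,
masking previously found sites with N between rounds. The whole procedure
is replicated `n_runs` = 100 times at each width in {6, 8, 10, 12} with
independent generators spawned from the master seed
(`np.random.SeedSequence(seed).spawn`), which makes the full candidate list
reproducible and independent of execution order.

Candidates are then sorted by score and greedily agglomerated: a candidate
joins the first group whose representative PWM lies within KL distance
`distance_threshold` = 0.3 (best ungapped offset, both orientations,
minimum overlap 4 columns); representatives are site-count-weighted column
averages at the founder's width. Groups found in fewer than
`min_runs` = 10 of the 100 runs are discarded (the validity rule — when
the run count is scaled down, scale `min_runs` proportionally: it encodes
a 10% reproducibility requirement, not an absolute count). Finally,
redundancy across widths is removed by keeping, among mutually similar
groups, the one found in most runs (ties: wider motif).

`n_iterations` (sweeps per motif, default 200) is a convergence knob: the
AT-rich composition of plant intergenic DNA creates attractive low-complexity
local optima, and under-converged runs are the dominant failure mode of
planted-motif recovery. Doubling iterations roughly halves the per-run miss
rate at moderate signal strength (~1.37 bits/column, 80% planting).

## Motif comparison and annotation

The distance between two PWM columns a, b is the symmetrised KL divergence
`Σ_base (a − b)·log(a/b)`; the distance between two PWMs is the column
average over the best ungapped alignment, `d = (1/2m)·Σ`, minimised over
all offsets with overlap ≥ 4 and both orientations. Probabilities are
floored at ε = 10⁻⁶ before logs. Annotation assigns each valid motif to the
nearest library PWM; distances above `annotation_cutoff` = 0.3 leave the
motif "novel". The 0.3 cutoff is the same threshold used for run grouping,
so "same motif" means the same thing in both places.

## Scanning

Two scanners with different contracts:

* **Locator-style** (`scan_normalized`): per-window raw score
  `Σ_i log(pwm[i, base] / P(base | context))` where the denominator uses
  the full k-order background conditioned on the actual preceding bases;
  the score is min–max normalised between the per-window extrema achievable
  under the same denominators, and a hit requires normalised score ≥ t
  (default 0.9). Used for mapping rates: a motif is *enriched* in a target
  promoter set when its mapping rate (fraction of promoters with ≥ 1 hit)
  exceeds `fold` = 1.5 × the rate in a random promoter sample — the
  "exceeds by more than 50%" rule. The literal alternative reading
  (target > 0.5 × random) is available as `mapping_rule: absolute` but is
  nearly always true and therefore not the default.

* **FIMO-style** (`scan_pvalue`): log-odds against the order-0 stationary
  background, mapped onto a 1,000-step integer lattice; the exact null
  distribution of the lattice score is computed by dynamic programming
  (per-position convolution), giving each window an exact p-value. Hits
  require p ≤ `p_threshold` = 10⁻⁴. Note the hard floor: a width-w motif's
  best possible p-value is the probability of its best word, so for w = 6
  no window can reach 10⁻⁴ even in the best case (0.25⁶ ≈ 2.4×10⁻⁴ under a
  uniform null). Families represented only by very short PWMs therefore
  need a relaxed `p_threshold` to produce hits; this is a property of exact
  p-values for short motifs, not an implementation limit.

Both scanners skip windows containing N and scan both strands. Consensus
sites are promoter intervals where hits of ≥ 2 distinct TF families
co-locate — exactly equal intervals by default (`colocate: identical`), or
connected components of the ≥ 1 bp overlap graph (`colocate: overlap`). A
gene is *marked* when its promoter carries more than one binding event or
any consensus site.

## Orthology and target propagation

Alignment hits (BLAST outfmt 6, optional 13th query-coverage column) are
ranked per query by bit score at read time; `top_hits` filters by e-value
(≤ 10⁻³), rank (top 10 to the intermediate species, top 5 direct), and
identity/coverage floors (30% / 50%). The high-confidence map joins
filtered query→intermediate hits to a curated intermediate→Arabidopsis
relation table; many-to-many relations are retained and the result is
deduplicated on (query transcript, Arabidopsis gene). A direct
query→Arabidopsis mode exists for species without a curated bridge. Joining
two tables with disjoint ID sets is a hard error (it almost always means an
ID-format mismatch, silently yielding an empty map otherwise).

Per TF family, the union of its Arabidopsis TFs' target genes is mapped
back through the ortholog map and intersected with the valid-promoter
universe, giving the family's gene universe for enrichment.

## Enrichment

For each family: universe N (its propagated target set), K DEGs among
them, n TFBS-carrying genes, k DEGs carrying a TFBS. The p-value is the
exact upper tail P(X ≥ k) of Hypergeometric(N, K, n) via
`scipy.stats.hypergeom.sf(k−1, N, K, n)`. Bonferroni control attaches the
per-test critical value α/m (m = number of families tested; with the
conventional α = 0.05 and m = 11 families, 4.55×10⁻³) and the decision uses the strict
inequality p < α/m. The lower tail is reported descriptively but never
enters the significance decision.

## Synthetic-data generator

`simulate` emulates, with known ground truth: promoters drawn from an
AT-rich order-0 background (stationary [0.31, 0.19, 0.19, 0.31]) with
motif occurrences sampled from chosen PWMs planted at non-overlapping
positions ≥ 2 bp from the edges; a toy genome in which each gene occupies
its own contig, laid out (on both strands) so that `extract_promoters`
returns the generated promoters byte-for-byte; DEG labels assigned first,
with planting probability conditioned on the label — so the DEG↔motif
association is a direct input, and `conditional_plant_probs` solves
(p_deg, p_nondeg) for any requested odds ratio and expected carrier count;
and self-consistent toy ortholog/alignment tables with decoy hits that
fall below the quality filters and optional dropout.

What it does **not** emulate: realistic gene density or overlapping gene
models (one gene per contig), higher-order background structure in the
promoters themselves, motif positional preference relative to the TSS,
paralogy/gene families in the ortholog tables, or expression data (DEG and
module lists are inputs by design — differential-expression detection is
out of scope).

## Numerical and reproducibility choices

- All stochastic components consume `numpy.random.Generator` objects seeded
  via `SeedSequence.spawn`, so results are identical across platforms and
  run orders; pipeline stages write manifests with input SHA-256 checksums.
- PWM probabilities are floored at 10⁻⁶ before any logarithm; motif-library
  round-trips preserve probabilities to 10⁻¹².
- The p-value lattice uses 1,000 integer bins; the DP survival function is
  clipped to ≤ 1 to guard against floating-point accumulation above 1.
- Background files store probabilities with full `repr` precision, so
  save/load round-trips are exact.

## Limitations

- Exact p-values are computed under the order-0 stationary null even when a
  higher-order background is configured (the higher order is used by the
  locator scan); this matches common practice but slightly miscalibrates
  p-values in strongly autocorrelated sequence.
- The greedy score-ordered grouping is order-dependent in principle; with
  the default threshold it is stable in practice (tested under candidate
  permutations), but pathological candidate sets could fragment a cluster.
- The mapping-rate rule is a point comparison without a significance test;
  it reproduces the original criterion rather than improving on it.
- Runtime: discovery is O(n_runs × widths × n_motifs × n_iterations × total
  promoter length); genome-scale studies need the run count reduced or the
  module restricted, as in the scaled configurations used by the tests.
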