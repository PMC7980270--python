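# Methods

This note documents the models behind `introscan`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions the implementation commits to.

## Coordinate and data conventions

All internal intervals are 0-based half-open; VCF and GFF3 coordinates
are converted at the I/O boundary (GFF3 start − 1), and every emitted BED
is 0-based half-open.  A `HaplotypePanel` stores phased biallelic alleles
as per-chromosome `(sites × haplotypes)` matrices in {0, 1, missing};
haplotype columns follow VCF sample order, two per sample, haplotype 0
being the left GT allele.  Multiallelic and indel records are skipped at
read time (not split) so everything downstream can assume biallelic SNPs.
Unphased heterozygous genotypes are rejected unless explicitly permitted,
since the IBD machinery is meaningless on unphased data.

## The coalescent generator

Each locus is an independent Hudson coalescent: within a population, *k*
lineages coalesce at rate *k(k−1)/2* per 2·N<sub>e</sub> generations;
populations merge backward in time at the configured split times.
Mutations follow the infinite-sites model — the per-locus count is
Poisson with mean (θ_locus/2)·T, where T is total branch length in units
of 2·N<sub>ref</sub> generations and θ_locus = 4·N<sub>ref</sub>·μ·L;
each mutation lands on a branch with probability proportional to its
length at a fresh uniform bp position (collisions resampled, so sites
stay biallelic by construction).  Time is kept in generations internally;
N<sub>ref</sub> is the effective size of the root population.

There is **no recombination within a locus and free recombination
between loci**; loci are tiled left-to-right into chromosomes (locus *i*
occupies [i·L, (i+1)·L)).  This preserves window-scale linkage — the
property the IBD and sweep scans rely on — at a fraction of the cost of
a full ancestral-recombination-graph simulator, but it means linkage
decays as a step function at locus boundaries rather than smoothly, and
long-range haplotype structure (e.g. for haplotype-length-based dating)
is not faithful.  Passing tests on this generator therefore demonstrate
correctness of the statistics and the recovery logic, not calibration of
the detector's operating characteristics on real recombining genomes.

Default parameters (chosen once, as study conditions, per scenario):

| parameter | default | rationale |
| --- | --- | --- |
| μ | 1.26 × 10⁻⁸ /bp/gen | the bovine rate used throughout the study domain |
| N<sub>e</sub> | 10,000 (all lineages) | round cattle-scale effective size |
| introgression scenario | donor 6, recipient 3, control 24 diploids | the donor/recipient/control sample sizes of the motivating design |
| splits | recipient/control 2,000 gen; donor 40,000 gen | desk-scale reduction of the taurine/indicine and cattle/yak divergences |
| locus length | 20 kb (introgression), 10 kb (sweep scans) | ≥ window step, several loci per window |
| genome | 1,000 loci (20 Mb / 10 Mb) | enough windows for stable top-5% quantiles at desk runtimes |
| tracts | 10 × 200 kb, copied onto 3 of 6 recipient haplotypes | tract ≫ window so the 20 kb rIBD scan is well-posed; an adaptively introgressed tract segregates at appreciable frequency, and 3 carriers keep the donor sharing signal (3/72 pairs) clearly above the background control×recipient IBS sharing (~1% of pairs) implied by the 2,000-generation control split |
| sweep | 100 kb region, θ_recovery = 0.05/locus | hard sweep with light mutational recovery |

The introgression overlay copies a randomly chosen donor haplotype onto
the selected recipient haplotypes over every site in the tract
(overlapping requested tracts are merged first so each base is copied
once).  The sweep overlay replaces every target-population haplotype in
the region with one "sweeping" haplotype and then adds per-haplotype
Poisson singletons — a star genealogy, which by construction yields
θ<sub>π</sub> ≈ 0, strongly negative Tajima's *D* and elevated
F<sub>ST</sub> in the region.  Both overlays record exact coordinates in
a `TruthSet`; recovery is scored at window resolution (a window counts as
truth if it overlaps a tract by ≥ 1 bp) plus a bp-level Jaccard.

## Windowed statistics

Windows are [k·step, k·step+size) while k·step < chromosome length, with
trailing windows truncated and flagged; per-bp statistics divide by the
window length in bp (the VCFtools sliding-window convention), so
invariant sites need not be present in the VCF.  This denominator choice
slightly deflates per-bp values in windows with much missing data — a
documented caveat, accepted for comparability with the standard
toolchain.

* θ<sub>π</sub>: per-site unbiased `2p(1−p)·n/(n−1)` with n the called
  haplotypes at the site (site skipped and counted when n < 2).
* Weir–Cockerham F<sub>ST</sub>: the per-site variance components
  a, b, c from diploid individuals (observed heterozygosity enters
  through h̄); a site is usable when every group has ≥ 1 called
  individual and the mean sample size exceeds 1 (the formulas divide by
  n̄ − 1).  Windowed F<sub>ST</sub> is Σa/Σ(a+b+c) — the ratio-of-sums
  ("weighted") estimator, the standard scan choice — and negative values
  are reported raw because clamping would distort the top-5% quantile.
* Tajima's *D*: computed per group on sites fully called in that group,
  keeping n constant as the 1989 normalising constants assume; k̂ uses
  the frequency form, which equals explicit pair counting.  *D* is
  missing when S = 0 or n < 4.
* D<sub>xy</sub>: per-site `p_A(1−p_B) + p_B(1−p_A)` over sites with ≥ 1
  called haplotype per group.
* θ<sub>π</sub>-ratio: reference/focal, with the log2 variant also
  emitted; missing when focal θ<sub>π</sub> = 0.  "Reference" is the
  non-extreme-environment group, so high ratios flag diversity loss in
  the focal group.  Both orientations are recoverable (the ratio and its
  reciprocal), since the field's usage of "relative polymorphism level"
  is direction-ambiguous.

## IBD detection and rIBD

True probabilistic IBD inference (fastIBD-style HMMs) is out of scope;
two input paths exist instead.  Externally inferred segments can be read
from a whitespace-delimited dialect (sample, haplotype index, sample,
haplotype index, chrom, start, end, score), with score thresholding left
to the reader's `max_score` since fastIBD scores are model-specific.
Alternatively the built-in detector finds long near-identical IBS runs:
for each cross-population haplotype pair, maximal greedy left-to-right
runs of sites whose mismatch count stays within `max_mismatch_frac`
(default 0.02) of the run's site count, kept when they span ≥ 50 kb and
≥ 25 sites, with bp bounds extended half-way to the neighbouring sites.
Sites with a missing allele count as matches.  Defaults suit the
simulator's tract scale (200 kb tracts vs 20 kb windows) and tolerate
post-introgression mutations.

Window sharing is **binary per haplotype pair** — a pair either has ≥ 1
segment overlapping the window or not — normalised by the pair-universe
size, so f ∈ [0, 1] and rIBD = f_control − f_donor ∈ [−1, 1].
Chunk-count normalisation was rejected as unbounded.  The sign convention
makes negative rIBD mean donor introgression; `flip_sign` is exposed for
the opposite convention.  Candidate regions are runs of ≥ 3 consecutive
windows with rIBD below 0 (both defaults overridable), merged across
gaps of at most one window step, scored by the minimum rIBD inside.

## Selection scan

Only windows with ≥ `min_sites` (default 10) variant sites are ranked;
quantiles are computed over rankable windows alone so the min-sites
policy cannot shift thresholds.  The joint cut takes windows in both
top-q tails (empirical k-th largest with k = ⌊q·n⌋, ties included at the
boundary, which keeps the cut deterministic without randomised
tie-breaking); requiring both F<sub>ST</sub> and the θ<sub>π</sub>-ratio
makes the neutral flagged fraction ≤ q by construction.  Tajima's *D* is
attached to regions as corroborative output and deliberately not used as
a third filter.  Genes are attached by ≥ 1 bp overlap under half-open
semantics; merging of flagged windows (gap ≤ step) and once-per-genome
gene counting are this package's own conventions.

## Trees, IBS and f3

Individual-level distances are genotype-dosage *p*-distances
(`mean |g_i − g_j|/2` over co-called sites), matching individual-resolution
phylogenies of sequenced animals rather than population-frequency
distances; IBS = 1 − d.  Note that the IBS baseline depends on the panel
composition: with only three lineages feeding the site table, unrelated
individuals within a population sit near IBS ≈ 0.90, whereas panels with
many breeds dilute within-population sharing well below the usual 0.9
duplicate screen.  The screen's invariant — duplicates at IBS ≈ 1, all
cross-population pairs well below threshold — is what the tests assert.

Neighbour joining uses the Studier–Keppler Q criterion with deterministic
smallest-index tie-breaking, standard branch-length formulas and an
unrooted 3-way root; it is exact on additive matrices (verified to 1e-9).
Negative branch lengths are kept and warned about, never clamped —
clamping is a display choice.  Optional outgroup rooting splits the
outgroup edge in half.

f3(T; A, B) uses the target-heterozygosity bias correction
`t = (a−b)(a−c) − a(1−a)/(n_a−1)` per site; the uncertainty is a
delete-one jackknife over contiguous genomic blocks (default 5 Mb;
smaller for desk-scale genomes, with ≥ 10 non-empty blocks enforced).
Unequal block sizes are handled by deleting whole blocks from the grand
sums; block-size weighting refinements were judged unnecessary at the
site counts involved.  Admixture fixtures rebuild the target as a
per-locus 50/50 mosaic of source haplotype copies — admixture with free
recombination between loci — which drives Z far below −3, while
unadmixed sister targets give clearly positive Z.

## Problem sizes and determinism

Desk-scale runs use 20 Mb (introgression) and 10 Mb (sweep) genomes,
500–2,000 loci for calibration, and 40 simulated datasets per arm for the
f3 behaviour check; the full validation completes in well under a minute
on one CPU.  All randomness flows through a single integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical panels,
and window tables are byte-stable given identical input.  Monte-Carlo
calibration checks have known sampling widths (e.g. the n = 2 π/θ ratio
has ~2.4% standard error at 2,000 loci, so its 5% band is a ~2σ test);
the estimators themselves were verified unbiased at larger replicate
counts.

## Known limitations

* No within-locus recombination, gene conversion, migration bands or
  selection in the genealogy itself — introgression and sweeps are
  overlays with exactly known truth, which is the point, but also means
  intermediate-strength or ancient signals are not represented.
* The IBS-run detector is a stand-in for probabilistic IBD inference;
  its thresholds are tuned to the simulator's tract scale and will need
  adjustment for real recombining data with genotyping error.
* Per-bp denominators assume windows are fully callable.
* Ploidy is fixed at 2 and sites at biallelic SNPs; BCF and indexed
  access are not supported.
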