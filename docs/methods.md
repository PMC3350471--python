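# Methods

This note documents the models, calibrations, and numerical choices behind
`mirsnpmech`, and what the synthetic studies do and do not demonstrate.

## Coordinates and conventions

All coordinates are 0-based half-open on the genomic forward strand;
writers emit the same convention.  Mechanism analysis happens on
transcript-sense sequence after strand correction.  A CLIP cluster's center
is `floor((start+end)/2)`; an MRE's position is the 5′ end of its
seed-complementary site; the 21-nt cluster-center distance bound is
inclusive.  When one SNP falls in several transcripts the localization
label follows the precedence CDS > 3′-UTR > 5′-UTR > intronic > intergenic;
the choice is echoed into run metadata.

## LD machinery

r² between phased haplotype columns is D²/(pA·pa·pB·pb), identical to the
squared Pearson correlation of the 0/1 columns; a squared dosage-correlation
fallback exists for unphased input.  Sentinel extension adds every panel SNP
with r² ≥ 0.8 (default) to at least one sentinel, restricted to a 1-Mb
same-chromosome window — unbounded search would be quadratic in panel size
and LD beyond 1 Mb is negligible for the block structure modeled here.

All-vs-all blocks are maximal cliques of the r² graph in principle; exact
maximum-clique binning is intractable, so binning is greedy and
order-stable: SNPs are visited in genomic order, each unassigned SNP seeds a
block, and later unassigned SNPs within the window join iff their r² with
*every* current member meets the threshold.  The output is a true partition
(verified against brute-force oracles in the tests), documented as a
heuristic.

## Enrichment statistics

The 2×2 odds ratio uses a Woolf (log-scale) CI; the Haldane–Anscombe +0.5
correction is applied to all four cells only when a cell is zero, and the
result is flagged.  Significance against "a random catalog of the same
size" is the resampled null: sentinels are drawn uniformly without
replacement, extended exactly as the observed set, and the in-class log-OR
recorded per replicate.  The empirical p reports the conservative maximum
of the rank-based exceedance (r+1)/(n+1) and the tail of a normal fit to
the null; both components are logged.  SNP-level, block-level, and
blocks-only (minimum block size) enrichment modes are available through
`class_table`.

A structural fact about this design worth knowing: with class-dependent
block sizes, LD extension of uniformly drawn sentinels preferentially pulls
in large intronic/intergenic blocks, so the *expected* extended-set 3′-UTR
OR of a random catalog sits below 1.  The generator therefore treats "no
enrichment" as *exchangeability with the null process* (uniform sentinel
draws), which makes the empirical p calibrated; a planted OR > 1 instead
calibrates the number of 3′-UTR-sourced sentinels against the realized
block composition so that the extended set's expected OR matches the
target.  Estimator checks (CI coverage of the planted value) are therefore
run at the planted OR = 4 condition.

Small utilities: Fisher's combined probability (χ² = −2Σln p on 2k df),
the rough FDR level α(m+1)/(2m), and the Pearson χ² test with a low-expected
-count flag.

## RNA structure model

The ensemble is pseudoknot-free secondary structures over Watson–Crick + GU
pairs with hairpin loops ≥ 3 nt.  The energy of a structure is a per-pair
formation cost (default +1.0 kcal/mol, a stand-in for loop entropy) plus
nearest-neighbor stacking energies from a published-style table; kT = 0.616
kcal/mol (37 °C).  This is deliberately not a full Turner model — no
dangles, no special loops — because the downstream statistic is a
*correlation of pairing tendencies between two sequences differing at one
base* under the same model, not an absolute free-energy prediction.  The
partition function and base-pair probability matrix are computed exactly by
an inside/outside dynamic program (numba kernels, O(n³)); exactness is
established against Boltzmann-weighted exhaustive enumeration on sequences
≤ 18 nt (max |ΔP| < 1e-9, in practice ~1e-14).

Pairing scores are BPP row sums (the probability each base is paired).  The
structure-change statistic is the Pearson ρ of the two alleles' 41-nt score
windows centered on a RISC site, truncated identically at sequence ends.
If both windows are constant they are compared directly (equal → ρ = 1, a
declared no-change; otherwise flagged NA and excluded from calibration and
calling); a single constant window is NA.

**Fold scope.**  Folding the whole 3′-UTR for every SNP × site pair is
cubic in UTR length and was judged a poor trade against the locality of
single-base structural effects; the pipeline folds a fixed 120-nt window
centered on the RISC site, and a SNP outside that window is scored ρ = 1
(no local effect considered).  Whole-sequence folding (with a configurable
4000-nt cap, truncation centered on the site) remains available via
`site_correlation` / `fold_window=None`.

**Threshold calibration.**  The FOLDING call threshold is the empirical
α-quantile (default α = 0.05) of min-ρ values over a null sample of random
non-sentinel 3′-UTR panel SNPs on cluster-bearing transcripts, min taken
per (SNP, transcript) over that transcript's sites.  Calls use strict
inequality (ρ < threshold), so at α = 0 no null SNP is called.  The
numerical threshold is data-dependent (≈ 0.68–0.88 across default-study
seeds); what is invariant, and tested, is the held-out type-I rate ≈ α.

## Poly(A) signals

The shipped default hexamer list is the 12 most abundant poly(A)-signal
variants (AATAAA, ATTAAA, TATAAA, AGTAAA, AAGAAA, AATATA, AATACA, CATAAA,
GATAAA, AATGAA, TTTAAA, ACTAAA), configurable at every call site.  A SNP is
in range when an annotated cleavage site lies 10–30 nt downstream in
transcript orientation.  All six hexamer frames of the 11-nt SNP-centered
window are scanned in both alleles; disruption and creation require the
signal set to empty or appear, a swap of one listed hexamer for another is
SYNONYMOUS (no call), windows truncated by the UTR end are used as-is and
logged.

## Splice-site scorer

The scorer is a trainable weight-matrix model with a logistic likelihood
calibration, not a neural-network reimplementation: the published
network's weights are unavailable, while the operational contract — a
likelihood in [0,1], a 0.5 retention cut, a 60-nt SNP-centered scan, the
gain/loss/increase/decrease taxonomy and border-distance retention filters —
is preserved.  Donor windows are 9 nt (3 exonic + GT + 4 intronic), acceptor
windows 23 nt (18 intronic + AG + 3 exonic); windows without the canonical
core score 0.  Matrices are per-position log-odds against a stated
background with additive pseudocount 1; the calibration is a 1-D logistic
regression of site identity on the PWM score, with core-bearing random
background windows as negatives upweighted 1.6:1 relative to balanced
classes so the 0.5 cut is conservative for non-sites.  On the synthetic
emission models this yields true-site likelihood ≥ 0.5 at ~91–95% and
random core-bearing windows ≥ 0.5 at ~2–4%.

Likelihood changes below 0.05 are ignored.  A gained site is always kept;
losses and likelihood shifts are retained only near an annotated junction
(acceptor −100..+10 nt, donor ±10 nt) under the default semantics — a loss
is only meaningful where an annotated site exists — with the opposite
reading available via `filter_semantics="exclude"`.  Distances are measured
in transcript coordinates (for 3′-UTR SNPs every scanned window is exonic,
so this differs from genomic distance only across introns, and gains are
unaffected).

**RISC-site loss.**  An acceptor gain excises the exonic interval from the
annotated upstream border (or transcript start) to the novel junction; a
donor gain excises from the novel junction to the annotated downstream
border (or transcript end).  The loss fraction is the share of the
transcript's cluster centers inside the excised interval.

## MRE calling

Canonical sites are the four standard seed-match types: 6mer (reverse
complement of miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1 (6mer + A
opposite position 1), 8mer (both), scanned exactly on transcript-sense
sequence with the most specific type reported per seed-core locus.
Functional sites require a same-transcript cluster center within 21 nt
(inclusive) and ≥ 1 sequencing read for the miRNA in that cluster.
Candidate miRNA pools are filtered by in-cluster enrichment: per miRNA, a
2×2 of seed-match counts inside vs outside cluster regions with
per-nucleotide opportunity correction, one-sided Fisher exact, kept at
BH-adjusted p < α (α configurable independently for the disruption and
creation pools, default 0.05 each).  Both pools are computed from the
reference UTRome: a created site does not exist in the reference, but the
miRNA's other genome-wide sites do, and they are what the filter measures.

A SNP disrupts a miRNA when a functional site overlapping the SNP exists
under the reference allele but not the alternate (or only a shorter type
remains); creation is symmetric, so extending an existing match to a longer
type counts as creation and the allele-swap duality
`disrupted(ref→alt) = created(alt→ref)` holds exactly.  Substitution =
both sets non-empty at one SNP.

Conservation: a SNP is conserved iff its (externally supplied) score
strictly exceeds 0.57; SNPs without scores are excluded from conservation
summaries.

## Synthetic data: what it emulates

The generator produces one chromosome of 24 genes (default) with 2–4 exons,
canonical GT/AG introns whose junction windows are drawn from the emission
models above, CDSs, and 200–2000-nt 3′-UTRs; ~35% of genes are on the minus
strand.  Poly(A) signal/site pairs are planted with the signal 16–28 nt
upstream of the cleavage site.  Defaults: 1200 background SNPs, 120
haplotypes, within-block r² target 0.9, 60 background sentinels, planted
3′-UTR OR 4, a 16-miRNA pool with 8 background clusters each (every cluster
centered on a genuine seed match), and planted effects {MRE disruption 3,
creation 3, substitution 2, acceptor gain 2, donor gain 1, poly(A) 2,
folding 2} plus 6 control SNPs.

Haplotypes use founder-copy-with-flips: within a block every haplotype
copies a founder allele and flips with probability ε = (1 − r²_target^¼)/2,
which realizes the pairwise r² target in expectation at founder frequency
0.5; only block-wise r² structure matters downstream, so no coalescent or
recombination-map machinery is used.  Blocks seeded at intronic/intergenic
SNPs average 5–6 members against 2 for exonic classes, emulating the less
extensive LD of exonic regions.

Planted effects are written into the reference genome so every ledger entry
is verifiable by direct sequence inspection (`verify_truth`).  Notable
constructions:

* **Substitutions** derive the second miRNA from the first by one seed
  change, so the same SNP destroys site A and completes site B at one locus.
* **Folding** plants a two-register switch: arms X = revcomp(S) upstream and
  Y = revcomp(S_alt) downstream of a central GC stem S inside inert A-runs
  that fill the fold window, so the reference allele pairs S:X and the
  alternate pairs S:Y.  Stems are redrawn until the isolated-construct ρ is
  < 0.5, guaranteeing every planted effect is a genuine structure switch
  rather than a marginal perturbation.
* **Effect miRNAs** receive four extra background clusters so the enrichment
  filter retains them by construction.
* **Controls** sit ≥ 150 nt from every cluster center (beyond the 120-nt
  fold window, so their ρ is exactly 1), ≥ 50 nt from junctions and poly(A)
  elements, and are screened to produce no splice-likelihood change and no
  poly(A)-hexamer change — they are no-effect SNPs by design, and the
  recovery criterion is that the pipeline calls none of them.

The catalog realizes its planted 3′-UTR OR by choosing the number of
3′-UTR-sourced sentinels against the realized block composition
(deterministic expectation, hypergeometric inclusion probabilities); at
OR = 1 sentinels are drawn uniformly (see the enrichment section).

**What passing recovery does not show.**  The synthetic genome is uniform
random sequence: it has no compositional biases, no isochores, no repeat
families, no real allele-frequency spectrum or recombination map, the
emission models are idealized, and planted effects are strong by design.
Recovery therefore validates the *machinery* — that each classifier detects
exactly the signal class it claims, at the calibrated false-positive level —
not the sensitivity of the method on real genomes.

## Problem sizes

The tests and the acceptance script use deliberately desk-sized studies:
the default study (1200 SNPs, 24 genes) for mechanism recovery; 700-SNP /
15-gene studies, 100 + 200 replicates, for enrichment-estimator coverage
and null calibration; 120-nt windows and 2 × 150 draws × 20 runs for the
ρ-threshold type-I check; 200 random sequences ≤ 18 nt for the
folding-oracle equivalence.  These sizes keep the whole suite in a few
minutes while leaving the statistical checks adequately powered (binomial
SE ≲ 0.005 on pooled rates).

## Known limitations

* The greedy LD binning is order-dependent by design (deterministic, but
  not the unique maximal-clique cover).
* The folding model ignores dangles, coaxial stacking, and loop-type
  energies; absolute pair probabilities are not comparable to full
  nearest-neighbor implementations, only the two-allele comparison is used.
* The splice scorer's likelihood is calibrated against synthetic
  backgrounds; on real genomes it would need retraining on annotated
  junctions.
* Enrichment modes other than SNP-level (block-level, blocks-only) are
  implemented and unit-tested but not exercised by the synthetic recovery
  studies.
* The MRE enrichment filter uses per-nucleotide opportunity, not a
  per-site accessibility model.
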