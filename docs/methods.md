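# Methods

This note records the models, parameter choices and numerical decisions
behind `clonekit`, and what the synthetic validation does and does not
demonstrate about real data.

## Genotype calling from read depths

A locus call depends only on the per-allele depth vector. With total depth
*n*, major count *c₁* and minor fraction *m* = (*n* − *c₁*)/*n*:

| condition            | call      |
|----------------------|-----------|
| *n* < `min_depth` (30) | NO_CALL |
| *m* ≤ 5 %            | HOM (minor reads treated as sequencing error) |
| 5 % < *m* ≤ 10 %     | DISCARDED (ambiguous band) |
| *m* > 10 %           | HET (major + second allele) |

Boundary convention: exactly 5 % is homozygous and exactly 10 % is
discarded (closed upper bounds). The source rules leave exactly-5 %
formally ambiguous; a single deterministic convention was fixed and made
configurable through `CallParams`. Comparisons run on integer counts
against `frac × total` (with a 10⁻⁹ relative epsilon) so grid boundaries
like 5/100 never flip on float rounding. Loci with more than two alleles
above the heterozygote threshold are discarded: the upstream assembly used
a single variant per locus and defines no tri-allelic semantics. In the
matrix builder, DISCARDED and NO_CALL both surface as missing, and sample
and locus order is sorted, making the result invariant to record order.

Because calls are diploidized, a polyploid's intermediate dosages all
surface as HET; true dosage reaches the pipeline only through depth (see
ploidy below). This mirrors how Stacks-style callers report polyploids.

## p-distance and partitioning

Between two samples, each locus where both calls are present contributes
0 (identical unordered pair), 1 (one shared allele) or 2 (no shared allele)
difference units; the distance is units/(2 × shared loci). This
allele-dosage convention is symmetric, reduces to the haploid p-distance on
homozygotes, and treats het-vs-hom as half a difference — whether the
original MEGA computation counted it as 0.5 or 1 is not documented, so this
convention is declared rather than asserted to match bit-for-bit. Pairs
with no shared loci get NaN and are reported, never zeroed.

Partitioning takes single-linkage connected components at distance
≤ 1 − cutoff (complete linkage available by flag); NaN pairs never link.
Groups are ordered largest-first with lexicographic tie-breaks. Raising the
cutoff can only refine the partition. The pipeline default cutoff (0.9978)
is the value used in the reference analysis of real data; the synthetic
scenario uses 0.75 (`SCENARIO_PARTITION_SIMILARITY`) because the generator
compresses "species divergence" into far fewer loci — see below.

## Heterozygous-locus clone similarity

Direction A→B compares every locus where A is heterozygous and B has any
call; a match requires the identical unordered genotype (an allele-sharing
mode is available, since the published description does not pin the match
rule down). The pair similarity is the mean of the two directional
percentages; a direction with zero comparable heterozygous loci is
undefined, and a pair with both directions undefined is incomparable.
Pairs with fewer than `min_overlap` (default 20) compared loci are flagged
unreliable but kept — the source never states a floor, and silent dropping
would bias the similarity curve.

Threshold calibration scans consecutive sorted similarity values whose
upper end does not exceed the smallest duplicate-library similarity and
takes the midpoint of the widest interval; a gap narrower than 5 points, or
absence of duplicates, falls back to the default 85 % with a warning. Any
duplicate pair at or below the final threshold aborts calibration — that
signature (a technical replicate resembling a different genotype) indicates
contamination, and in the reference workflow such libraries were rebuilt.
Clones are connected components of the ≥-threshold graph; components
containing an internal below-threshold pair are kept but reported as
transitivity violations, since the statistic is expected to be strongly
bimodal and violations signal either contamination or a threshold placed
inside a cluster.

## Allele-balance ploidy inference

At a heterozygous locus with minor-allele dosage d of p, reads follow
Binomial(n, d/p), so pooled minor fractions pile up near min(d, p−d)/p.
The spectrum uses the top-two-allele denominator (the normalised pair
ratio, matching kmer-pair logic; total-depth denominator differs only
through sub-cut-off noise alleles), a minimum coverage of 20 and a 5 %
allele cut-off. Only peak positions are interpreted: locus coverage in
reduced-representation data is far from uniform, so peak heights carry no
ploidy signal.

Numerical choices in peak detection, all of which exist to make positions
stable under sparse, overdispersed data:

* **Fold-bias removal.** The minor fraction lives in (0, 0.5], so a diploid
  peak sits exactly on the fold and a naive histogram mode lands one to two
  bins below 0.5. Every fraction f is mirrored to 1 − f, maxima are found
  on the symmetric (0, 1) histogram, and positions are folded back. Mirror
  twins collapse onto a single reported peak.
* **Smoothing and maxima.** 0.01-wide bins, 3-bin moving average,
  `scipy.signal.find_peaks` with a minimum separation of 0.05 (distinct
  dosage fractions are never closer than the 1/5-vs-1/4 gap), a plateau cap
  (a plateau wider than the separation scale is structureless noise, not a
  peak — this makes an exactly uniform histogram peakless), and a
  topographic prominence of ≥ 25 % of the tallest smoothed bin, which
  rejects noise bumps riding on a real peak's flank.
* **Mean-shift centroids.** Each maximum is refined to the mean of the raw
  mirrored fractions within ±0.05 of the moving centre (flat-kernel
  mean-shift). This decouples the reported position from bin placement;
  without it the centroid jumps by up to ±0.8 percentage points depending
  on which bin the argmax lands in.
* **Mass filter.** A peak must hold ≥ 10 % of total spectrum mass within
  its window.

Ploidy assignment picks the smallest p in 2..`max_ploidy` (default 8) such
that every peak lies within `tolerance` (default 0.03, chosen to separate
1/3 from both 0.25 and 0.40) of the allowed set {min(d, p−d)/p} *and* the
lowest peak matches 1/p. The anchor prevents a lone 0.25 peak from reading
as octoploid, and the smallest-p rule encodes parsimony — in the reference
workflow, chromosome counts played this arbitration role. If no p fits,
the best-effort p is returned with `consistency=False` rather than raising:
an inconclusive spectrum is a result, not an error.

The merge-stability check rebuilds spectra per library set and for their
union; peaks must agree within one bin width. Clonal libraries sharpen the
signal without moving peaks; mixing ploidies (or non-clonal material)
shifts or duplicates them.

## Genome-size arithmetic

Replicate 2C measurements are accepted with ≥ 3 daily replicates and
max/min ≤ 1.02, or failing that SEM/mean < 1 % (SEM = sample sd/√n; the
estimator is not specified in the source, so the conventional one is used).
1Cx = 2C/ploidy rounded half-up to 3 decimals — half-up (not banker's)
rounding is required to reproduce all published 1Cx values, e.g.
2.290/4 = 0.5725 → 0.573. Published 2C means are used as the conversion
input; this reproduces the printed 1Cx column exactly for every taxon.
Theoretical 2C ranges multiply the ploidy by the min/max of diploid 1Cx
anchors; the tetraploid falling below its range is the genome-downsizing
signature. Intraspecific variation is 100 × (max − min)/min.

## Breeding-system rules

The rule cascade (males ⇒ sexual; testable multi-clone ⇒ sexual; testable
uniclonal solitary over ≥ 2 localities ⇒ apomictic; untestable ⇒ ploidy
parity, flagged inferred; uniclonal stoloniferous ⇒ apomictic but flagged
inconclusive because vegetative spread mimics the pattern) is a
codification of published reasoning that was never stated as an algorithm.
Clonality is treated as *untestable* when fewer than two samples exist or
when distinct wild localities are unknown (cultivated/imported material);
a single multi-sampled wild population remains testable, since distinct
individuals from one locality can still reveal multiple clones. Even
ploidy defaults to sexual-inferred — even-ploidy apomicts exist, hence the
explicit `inferred` flag on every ploidy-based call. A missing ploidy
where the parity rule is needed raises rather than guessing.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* Per-taxon allele frequencies drawn from Beta(0.5, 0.5) per locus (an
  uninformative, U-shaped site-frequency prior giving ~25 % heterozygous
  loci in diploid founders, ~750 of 2000 loci in triploids); taxa draw
  independently, so between-taxon distances (~0.4) dwarf within-taxon ones
  (≤ ~0.13 for full sibs).
* Clonal taxa: one founder genotype per clone, shared by all ramets and
  duplicate libraries. Sexual taxa: diploid sibships by Mendelian gamete
  union from two parents (no selfing).
* Depths: negative binomial with mean 250 and dispersion 0.3
  (variance = μ(1 + 0.3μ)), emulating reduced-representation
  overdispersion; per-read substitution error 0.001 flips alleles.
* Diploidized emission with heterozygote→homozygote dropout at 0.005 per
  library (allelic dropout being the dominant RAD genotyping error mode);
  cells under 30 reads are emitted as missing, coupling genotype
  missingness to depth as in real calling.
* Duplicate libraries: at least one per taxon, others at rate 0.15
  (matching the reference study's 20 duplicates per 137 samples).

The default scenario mirrors the shape of the study system: a widespread
uniclonal solitary triploid (12 ramets, 12 localities), a single-locality
stoloniferous sexual diploid producing 8 distinct sib clones, and a
uniclonal solitary pentaploid (6 ramets). All randomness flows from one
seeded generator, so outputs are byte-reproducible.

**What passing means, and does not mean.** The generator reproduces the
*contrasts* the method exploits (clone mates ≈ duplicates ≫ sibs; dosage
fractions at d/p; overdispersed depth) but not every feature of real
ddRADseq: no linkage, no restriction-site polymorphism or locus dropout
correlated with phylogeny, no cross-sample contamination, no per-locus
paralogy. In particular, real species diverge at a small fraction of a
large locus set, while the generator compresses divergence into 2000 loci;
the partition cutoff that separates taxa therefore sits at 0.75 here versus
0.9978 on real data. Perfect clone precision/recall on simulations shows
the statistic and thresholding behave correctly under the stated error
model, not that any real data set will show as clean a gap — the reference
analysis itself found one group with a narrower, dataset-specific gap.

## Problem sizes and runtimes

Defaults were chosen so the entire validation is interactive: 2000 loci,
~30 libraries, depth mean 100–250×; the full pipeline runs in ~1 s, the
whole test-suite (including 400 ploidy-recovery replicates and the
end-to-end run) in ~10 s, and the acceptance script in a few seconds.

## Known limitations

* Similarity and distance computation is O(n² m) pairwise loops; adequate
  for hundreds of libraries, not thousands.
* Genotype likelihoods, base qualities and probabilistic error models are
  out of scope; calling is threshold-based by design.
* The ploidy caller reports a single best p per spectrum; mixed pools
  (e.g. accidentally merged non-clonal libraries) are flagged by the
  merge-stability check rather than deconvolved.
* Breeding-system calls inherit the biological caveats of their rules:
  stoloniferous uniclonal taxa stay inconclusive, and ploidy-parity
  inferences are labelled as such.
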