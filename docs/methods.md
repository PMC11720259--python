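# Methods

This note records the model, the numerical choices, and what the synthetic
data can and cannot show. It documents decisions; every empirical number it
mentions is computed by the test suite or the acceptance script, not here.

## Genotype representation and I/O

Genotypes are phase-free codes (HOM_REF / HET / HOM_ALT / MISSING) over a
position-sorted marker map, 1-based inclusive coordinates as in PLINK MAP
files. All ROH logic depends only on hom/het/missing, so allele labels are
a bookkeeping convention: pairs are stored lexicographically sorted, and a
SNP observed with a single allele is coded HOM_REF for that allele
("observational" coding). PED text carries no allele metadata beyond the
calls themselves, so this convention is exactly what a reader can
reconstruct — it makes write→read an identity on codes, and every
downstream statistic is invariant to the relabelling (tested).

Half-called pairs (`A 0`) are treated as missing, as PLINK does.

## Quality control

Two call-rate filters plus an autosome restriction, with deliberately
different comparators mirroring common reporting language: SNPs are kept at
call rate **≥** 0.90 ("at least 90%"), individuals at call rate **>** 0.95
("more than 95%"). Both comparators and the stage order (SNP → individual →
autosome by default) are configurable and logged, because the order is a
genuine free choice: the filters interact through the recomputed call
rates. For the same reason sequential filtering is not idempotent for
entities sitting exactly at a threshold; at array-realistic missingness
(~0.5%) rates sit far from the thresholds and reapplication is a no-op
(tested).

Observed heterozygosity is the heterozygote fraction of non-missing calls;
expected heterozygosity is 2p(1−p) from the non-missing allele frequency,
with no small-sample correction, so population means are exactly
reproducible from the per-SNP table. The Hardy–Weinberg test is the exact
enumeration test over heterozygote counts conditional on allele counts
(two-sided, probability-mass ordering; mid-p off by default); a chi-square
variant exists for speed but the exact test is the default because its
values can be checked against a rational-arithmetic oracle. Monomorphic
SNPs get p = 1 by convention.

## ROH detection

Sliding-window scan with parameters defaulting to a 70k-equine-array
analysis: window 52 SNPs, min 52 SNPs per run, support threshold 0.05, max
gap 1 Mb, min length 1 Mb, 0 heterozygotes and ≤ 1 missing call per
window. Details that needed fixing:

* Windows are fully contained in the chromosome; SNPs near the ends are
  covered by fewer windows and support is normalized per SNP by the
  windows actually covering it. Chromosomes with fewer SNPs than the
  window yield no calls.
* The support comparator is inclusive (≥ 0.05) *at the printed decimal*: a
  SNP covered by 20 windows of which 1 is homozygous passes, even though
  the binary float 0.05 is infinitesimally above 1/20. Implemented with a
  1e-9 tolerance; the brute-force oracle in the tests uses the same
  definition.
* A missing call is never counted as heterozygous; it only consumes the
  missing budget. A corollary worth knowing: two missing calls within one
  window span legitimately split an otherwise clean run, because every
  window containing both fails the budget.
* Runs are split at gaps > 1 Mb *before* the SNP-count/length/density
  filters are applied.
* `length_bp = end_bp − start_bp` (no +1), matching how such intervals are
  usually tabulated.
* The minimum-SNP formula L = ln(α/(n_s·n_i))/ln(1−het) is rounded
  half-up (52.005 → 52).
* The density floor defaults to 1 SNP per Mb of run span. A floor of
  1 SNP per 10 kb — a value sometimes quoted for this scan family — cannot
  be meant literally for a ~64k-SNP array covering ~2.28 Gb (~1 SNP per
  36 kb on average): it would reject every run regardless of
  homozygosity. One SNP per Mb is the effective floor of the widely used
  sliding-window implementation this scan mirrors; the parameter is fully
  configurable in SNPs per bp.
* Whether a run's terminal SNPs must themselves be non-missing is left as
  detected (boundaries may be missing-flanked), matching the reference
  implementation's behavior.

The scan is vectorized per chromosome (cumulative-sum window counts) and
verified against a literal enumerate-every-window oracle on randomized
small instances, including randomized parameters.

## Inbreeding decomposition

F_ROH = ΣL_ROH / L_genome with L_genome either supplied (default constant
2,276,871,601 bp, the SNP-covered autosomal length of the emulated array)
or recomputed as Σ(last − first SNP position) per chromosome. Chromosome-
scope records divide by the chromosome's covered length; per individual,
chromosome-scope ΣL_ROH sums to the genome-scope value (tested).

Generation thresholds are 100/(2g) Mb **truncated** (not rounded) to one
decimal — 16.6, 8.3, 5.5 Mb for g = 3, 6, 9 — because truncation is the
rule consistent with all three published values (rounding would give 5.6
for g = 9). The comparator at the boundary is inclusive (run length ≥
threshold), and the threshold in bp is the exact integer round(t·10⁶) so a
run of exactly 16,600,000 bp counts (the naive float product is
infinitesimally larger). F_ROHANC = F_ROH − F_ROH9G, i.e. the component of
the deepest generation supplied is subtracted.

Cohort summaries report mean ± SD per component and each component's share
of mean F_ROH, rounded half-up to integer percent.

## Island test

The null treats run placement as uniform: the randomized incidence is an
integer drawn uniformly on {0, …, M_k} inclusive, M_k the chromosome's
maximum incidence. The reported p is the upper tail P(r ≥ c) =
(M_k − c + 1)/(M_k + 1), so small p marks enrichment and ties count toward
the tail (conservative, and it makes the closed form exact). The
lower-tail reading P(c > r) — the literal transcription of "actual
incidence exceeded the randomized" — is available behind `tail="literal"`
but is inconsistent with a small-p significance rule and is not used for
calling. Monte-Carlo mode reproduces the closed form to binomial sampling
error (tested at 10⁵ draws, 4σ) and uses one seeded stream per chromosome,
chromosomes in ascending order, so results are reproducible and
independent of chromosome processing order.

Islands: maximal stretches of consecutive SNPs with in-ROH frequency
≥ 0.5 — the frequency condition applies to *every* SNP of the stretch, the
stricter of the two plausible readings — reported when ≥ 3 SNPs have
p < 0.01. `mean_p` averages all stretch SNPs (not only significant ones).
Boundaries are SNP positions; BED export converts to 0-based half-open.

A structural consequence of the null worth noting: p < 0.01 is attainable
only when M_k ≥ 100, since min p = 1/(M_k + 1). Island calling therefore
needs cohorts of a few hundred individuals — which the emulated study has
(n = 506) — and this drives the problem sizes in the recovery tests below.

Annotation reports a gene for an island on ≥ 1 bp closed-interval overlap
(full containment behind a flag); "within" readings differ across studies
and overlap is the weaker, safer default.

## Synthetic populations

The generator emulates the study cohort: 31 autosomes with horse-like
relative sizes rescaled to sum exactly to 2,276,871,601 bp; 64,203 SNPs
apportioned by length (largest-remainder rounding) with uniform positions;
background heterozygosity 0.32 via allele frequencies from a symmetric
Beta(a, a) with a = h/(1 − 2h) (closed form from E[2p(1−p)]); missing rate
0.005; genotypes drawn per-SNP under Hardy–Weinberg, independent across
SNPs.

Planted structure: per individual, Poisson-many homozygous tracts per
length class with expected counts (60.8, 10.0, 7.3, 1.5) — the emulated
landscape's ~79.5 runs/individual split roughly 76/13/9/2% across the
<5.5 / 5.5–8.3 / 8.3–16.6 / ≥16.6 Mb classes — with lengths uniform within
class. The short class is floored at 2 Mb: at ~28 SNPs/Mb a tract under
~1.85 Mb carries fewer than the 52-SNP detection minimum, and the
landscape being emulated is itself one of *detected* runs, already subject
to that floor. Island regions overwrite a chosen span with the
major-allele homozygote in a chosen fraction of individuals. Ground truth
(tracts, island carriers, per-individual planted coverage q as a union
fraction) is returned alongside the genotypes.

What the generator does **not** model: linkage disequilibrium, recombination
maps, pedigree structure, allele-frequency clines, array ascertainment
bias, and genotyping error outside planted tracts (a per-SNP
heterozygote-error rate inside tracts exists to exercise the window
budgets). Passing recovery tests therefore demonstrate the *detection and
accounting machinery* — window logic, length decomposition, the island
null — not robustness to LD-induced chance homozygosity, which in real
arrays is precisely what the L formula and the 52-SNP floor guard
against. Independence makes that guard conservative here: the chance of a
spurious 52-SNP homozygous window is (1 − het)⁵² ≈ 1.6×10⁻⁹.

## Problem sizes in the tests

Oracle-equivalence tests run on ≤ 200 SNPs × ≤ 5 individuals (100 random
instances). F_ROH recovery runs one cohort of n = 50 on the full
31-autosome genome at the emulated density; detected F_ROH tracks planted
coverage within 0.01 (the residual is the detectability floor plus
per-tract edge effects of under a window span). Island recall runs 20
seeds at n = 506 — the cohort size the null requires, see above — on a
4-chromosome genome at the same density and the same per-bp background
coverage, which preserves every per-chromosome quantity the test depends
on while keeping each replicate small. The worked example in the README
uses a 4-chromosome, 200-individual toy for speed.

## Known limitations

* No LD or demographic realism in the generator (see above).
* The PLINK binary (.bed) dialect is not read; PED/MAP text is the
  supported interchange format.
* The exact HWE test enumerates per SNP; for cohorts far larger than a few
  thousand individuals the chi-square option is the practical choice.
* Sequential QC is order-dependent by nature; the manifest records the
  order used.
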