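# rohscan

Runs-of-homozygosity (ROH) analysis for SNP-array genotypes: genomic
inbreeding with a recent/ancestral decomposition, and detection of ROH
islands as candidate selection signatures.

## Who this is for

Animal and population geneticists characterizing inbreeding in a genotyped
cohort — typically a livestock or horse breed genotyped on a medium-density
array (tens of thousands of SNPs across the autosomes) — when pedigrees are
shallow or unreliable and a molecular inbreeding estimate is needed.

## What it computes

**ROH detection.** A sliding-window scan in the style of PLINK
`--homozyg`/detectRUNS: every window of *w* consecutive SNPs is scored
homozygous when it contains no heterozygote and at most one missing call; a
SNP is "in a run" when at least 5% of the windows covering it are
homozygous; maximal in-run stretches are split at inter-marker gaps above
1 Mb and kept when they span ≥ 52 SNPs, ≥ 1 Mb, and satisfy a SNP-density
floor. The minimum SNP count guarding against chance runs is

```
L = ln( α / (n_s · n_i) ) / ln(1 − het)
```

with α the tolerated fraction of false-positive ROH, *n_s* SNPs per
individual, *n_i* individuals, and *het* the mean heterozygosity; for a 70k
equine array cohort (n_s = 64,203, n_i = 506, het = 0.323, α = 0.05) this
gives L = 52.

**Inbreeding.** For each individual,

```
F_ROH = Σ L_ROH / L_genome
```

at genome and per-chromosome scope. Under Fisher's recombination theory an
autozygous segment inherited from an ancestor *g* generations back has
expected length 100/(2g) cM (≈ Mb), so runs ≥ 16.6, 8.3 and 5.5 Mb date
inbreeding within the last 3, 6 and 9 generations (F_ROH3G, F_ROH6G,
F_ROH9G); the remainder F_ROHANC = F_ROH − F_ROH9G reflects older events.

**ROH islands.** Each SNP's incidence *c* is the number of individuals
whose ROH covers it. Against a uniform null on {0, …, M} (M = the
chromosome's maximum incidence) the enrichment p-value is the exact upper
tail (M − c + 1)/(M + 1), optionally estimated by Monte-Carlo. Islands are
maximal stretches of consecutive SNPs present in ROH of ≥ 50% of
individuals that contain at least three SNPs with p < 0.01; islands are
then intersected with gene annotation (BED/GFF3).

Because real cohorts of this kind are rarely shareable, the package ships a
synthetic-population generator with planted homozygous tracts, shared
island regions and full ground truth, used throughout the test suite.

## Worked example

```python
import rohscan as rs

cfg = rs.SimConfig(
    seed=42,
    n_individuals=200,
    chromosomes=tuple(rs.ChromosomeSpec(i + 1, 80_000_000, 2256) for i in range(4)),
    tracts_per_class=(8.5, 1.4, 1.0, 0.2),
    islands=(rs.IslandSpec(chromosome=3, center_bp=40_000_000, span_bp=3_000_000,
                           carrier_fraction=0.6),),
)
genotypes, truth = rs.simulate_population(cfg)

model = rs.ROHInbreedingModel(genotypes)
results = model.fit()
print(results.summary())
```

```
ROH inbreeding analysis
============================================================
Individuals: 200    SNPs: 9024    Chromosomes: 4
Mean Ho: 0.265    Mean He: 0.286
Window/min SNPs: 52/52
ROH detected: 1846 (9.2 per individual)
Mean ROH length: 5.90 Mb
------------------------------------------------------------
Inbreeding coefficients (mean +/- SD, share of F_ROH):
  froh       0.1703 +/- 0.0605
  froh_3g    0.0256 +/- 0.0437   15%
  froh_6g    0.0689 +/- 0.0580   40%
  froh_9g    0.0967 +/- 0.0629   57%
  froh_anc   0.0736 +/- 0.0286   43%
------------------------------------------------------------
ROH islands called: 1
  island 1: chr3 38,584,715-41,429,275 (2.84 Mb, 93 SNPs, mean p = 0.0267)
```

Reading the output: mean observed heterozygosity (0.265) sits below the
generator's background target (0.32) because a sixth of each genome lies
inside planted homozygous tracts. Each individual carries ~9 runs on this
4-chromosome toy genome; mean F_ROH ≈ 0.17 matches the planted coverage,
and 43% of it comes from runs too short to date within nine generations.
The one called island is the planted 60%-carrier region on chromosome 3
(centre 40 Mb), recovered to within a window span of its true boundaries.

`results.segments_frame()`, `results.inbreeding_frame()`,
`results.islands_frame()` and `results.annotate(genes)` expose the tables;
`rohscan.plot` draws the per-chromosome stacked F_ROH bars and the
incidence Manhattan plot.

The same analysis is available from the shell:

```sh
rohscan simulate --seed 42 --n 200 --out cohort
rohscan run --ped cohort.ped --map cohort.map --out report/
```

which writes the full report bundle (QC tables, segments, length classes,
inbreeding coefficients, incidence track, islands as CSV and BED, and a
`run_manifest.json` recording every parameter, comparator and seed).

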