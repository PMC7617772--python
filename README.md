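# invrad

Detection, genotyping and evolutionary analysis of large polymorphic
chromosomal inversions from population SNP data.

Large inversions suppress recombination between the inverted and ancestral
chromosome arrangements in heterozygotes. Across a species radiation this
leaves a characteristic multi-signal footprint in whole-genome SNP data:
genomic regions whose local sample-relationship structure departs from the
genome-wide pattern (three karyotype clusters in a windowed principal
coordinate analysis), strongly elevated heterozygosity in heterokaryotypes,
zero crossovers inside the region in pedigrees, excess allele sharing between
clades that exchanged inversion haplotypes, an excess of protein-changing
substitutions between the two arrangements when the haplotypes diverged under
selection, and Hardy–Weinberg heterozygote excess where an arrangement has
been recruited into XY-like sex determination. `invrad` implements the full
analysis chain for these signals, together with coalescent and forward
simulators that generate data with planted truth for every one of them.

## What it computes

| Stage | Statistic / method |
| --- | --- |
| Region detection | per-window pairwise-distance PCoA, iterative k-means outlier clustering |
| Inversion genotyping | panel PCA + 1-D k-means (k ∈ {2,3}), outgroup orientation polarity, het SNPs per 10 kbp |
| Rephasing | class-consensus phasing of heterozygous SNPs by inversion genotype; carrier-haplotype extraction |
| Selection | inversion-correlated SNPs (Pearson r, −log₁₀ p), exonic enrichment, McDonald–Kreitman Dn/Ds/Pn/Ps with NI and DoS, correlation-binned dN/dS with Nei–Gojobori site counts, shared-polymorphism fraction |
| Introgression | pairwise divergence times t = d/(2μ), Patterson's D = (ABBA−BABA)/(ABBA+BABA) with block-jackknife Z, inversion-state-conditioned D, coalescent ILS retention exp(−t/(2Nₑ)) |
| Association | Levene exact heterozygote-excess test, Fisher's-method pooling, Fisher exact genotype–sex tests, Mendelian 1:2:1 χ² |
| Simulation | msprime-backed clade radiation with planted inversions/introgression/sex linkage; pedigree cross with recombination suppression; two-background Wright–Fisher forward simulator of coding selection |

## Worked example

Simulate two clades (52 ingroup samples) plus an outgroup with one inversion
segregating at frequency 0.5, then detect and genotype it:

```python
from invrad import (GenomicRegion, simulate_radiation, genotype_region,
                    compute_window_profiles, align_pc_signs,
                    detect_outlier_regions, WindowSpec)
from invrad.region_detection import genomewide_profile
from invrad.cli import default_scenario, scenario_from_dict

dataset, metadata, truth = simulate_radiation(scenario_from_dict(default_scenario(1)))

profiles = compute_window_profiles(dataset, WindowSpec(200_000, 100_000, 25), n_pcs=2)
align_pc_signs(profiles, genomewide_profile(dataset, n_pcs=2))
calls = detect_outlier_regions(profiles, k_clusters=2, min_run=3, seed=1)
print(calls[0].region)

outgroups = metadata.samples_for("clade", "outgroup")
call = genotype_region(dataset, calls[0].region, outgroup_samples=outgroups, seed=1)
truth_gt = truth.inversion_genotypes.iloc[:, 0].to_numpy()
print("genotyping accuracy:", float((call.genotypes == truth_gt).mean()))
print("het SNPs per 10 kbp by genotype:",
      {g: round(float(call.het_per_10kb[call.genotypes == g].mean()), 2)
       for g in (0, 1, 2)})
```

Output:

```
GenomicRegion(chrom='chr1', start=1900001, end=5100000)
genotyping accuracy: 1.0
het SNPs per 10 kbp by genotype: {0: 0.24, 1: 3.56, 2: 0.19}
```

The detected region matches the planted inversion (chr1:2,000,001–5,000,000)
to within one 200 kbp window on each side, every sample is genotyped
correctly, and heterokaryotypes carry ~15× the SNP heterozygosity of either
homokaryotype — the diagnostic signature of two divergent, non-recombining
haplotype classes.

The same pipeline runs end to end from the command line:

```bash
invrad all --seed 1 --out results_dir      # built-in smoke scenario
invrad all --config run.toml --out out --seed 1
```

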