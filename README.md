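# rehhscan

Multi-breed selection-signature scanning on phased SNP-chip haplotypes using
relative extended haplotype homozygosity (rEHH), plus a forward Wright-Fisher
simulator for generating multi-breed datasets with known sweeps, pedigree
structure and QC defects.

The pipeline:

1. **qc** — two-step quality control: per-sample call rate, replicate
   concordance, sire/son Mendelian checks; then marker missingness, per-breed
   missingness, MAF, autosome/position filters. Relatedness pruning (remove
   genotyped fathers, cap half-sib families at five) yields the
   "non-redundant" dataset.
2. **ld** — pairwise haplotype r² and the within-breed LD decay curve up to
   1 Mb.
3. **cores** — automatic core-haplotype detection: contiguous spans of 3–20
   SNPs in which ≥95% of informative pairs are in strong LD under a
   |D′|-confidence-interval rule; longest non-overlapping spans are kept.
4. **ehh** — EHH decay per core allele, pooled-other EHH, relative EHH
   (up- and downstream at a configurable genetic test distance, default
   0.25 cM under the 1 cM/Mb map), and haplotype bifurcation trees.
5. **significance** — empirical rEHH significance: 20 frequency bins of 5%,
   within-bin natural-log transform, one-sided normal upper-tail p-values;
   core alleles with frequency > 25% are retained for reporting.
6. **multibreed** — significant cores sharing ≥1 SNP across ≥2 breeds of the
   same production type become shared regions; summaries and gene overlap
   against a local BED/GFF3 annotation.
7. **simulate** — forward Wright-Fisher populations with Haldane
   recombination on the marker map, selective sweeps (additive fitness
   1 : 1+s : 1+2s, optionally shared ancestral variants across breeds),
   breed splits, sire/half-sib pedigrees, replicates, missingness and
   genotype errors. Fully deterministic under a seed.

## CLI

All functionality is exposed through the `rehhscan` command:

```bash
rehhscan simulate --config sim.yaml --out data/           # synthetic data
rehhscan qc --ped a.ped --map a.map --pedigree ped.tsv --out qcdir/
rehhscan ld --vcf breed.vcf --out ld.tsv
rehhscan cores --vcf breed.vcf --out cores.tsv
rehhscan scan --vcf breed.vcf --breed HOL --out scan.tsv --test-distance-cm 0.25
rehhscan significance --scan-table scan.tsv --out sig.tsv --alpha 0.05
rehhscan run --config run.yaml --out results/             # full pipeline
```

A `run` config (YAML or JSON) names per-breed phased VCFs, production groups
and parameters:

```yaml
seed: 1
breeds:
  HOL: {vcf: hol.vcf}
  BRW: {vcf: brw.vcf}
  SIM: {vcf: sim.vcf}
groups:
  dairy: [HOL, BRW, SIM]
params:
  test_distance_cm: 0.25
  alpha: 0.05
annotation: genes.gff3   # optional
```

Outputs are plain TSVs (`core_alleles.tsv`, `shared_regions.tsv`,
`chromosome_summary.tsv`) plus a JSON manifest with the config hash and
output checksums; reruns with the same config and inputs are byte-identical.

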