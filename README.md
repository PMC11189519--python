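# relictpop

Population-genomic analysis toolkit for small relict cohorts, built around an
all-sites (variant + invariant) VCF workflow:

- **variant_store** — cohort dosage matrix, all-sites VCF 4.2 I/O, the
  vcftools-style filter cascade (missingness, allele count, MAC/MAF, mean
  depth, indel removal), invariant/variable splitting, concatenation,
  outgroup merging, and genic-interval (BED) extraction.
- **diversity** — missing-data-aware windowed nucleotide diversity (pi),
  between-group divergence (dxy), Weir–Cockerham (1984) Fst (Hudson variant
  behind a flag), per-individual heterozygosity and F_IS with the
  small-sample correction, and Yang-style Ajk relatedness.
- **linkage** — pairwise genotype-dosage r² within a distance cap, LD-decay
  curves with replicate downsampling, and windowed `--indep-pairwise`-style
  greedy pruning.
- **structure** — PCA on 2p-centered / sqrt(2p(1−p))-scaled genotypes,
  1-IBS allele-sharing distances, a from-scratch Saitou–Nei neighbor-joining
  implementation with deterministic tie-breaking, outgroup rooting, and
  Newick output (trees are `dendropy.Tree` objects).
- **neutrality** — folded site frequency spectrum from called genotypes and
  sliding-window Tajima's D with the full 1989 constants.
- **novel_alleles** — classification of alleles absent from a wild+outgroup
  reference panel and the exact-subset (UpSet-style) overlap decomposition.
- **simpop** — a forward Wright–Fisher simulator (piecewise-constant Ne,
  splits, migration, partial selfing, recombination, infinite-sites
  mutation on a two-subgenome chromosome layout) that generates all-sites
  cohort VCFs with a known truth record. Desk-scaled presets:
  `neutral_equilibrium`, `two_deme_island`, `domestication_series`,
  `island_relict`, `full_cohort`.
- **pipeline** / **cli** — end-to-end orchestration with a checksum
  manifest and stage skipping.

## CLI

```bash
# synthesize a 67-sample cohort (65 ingroup + 2 outgroup) as an all-sites VCF
relictpop simulate --preset full_cohort -L 60000 --seed 42 \
    --out cohort.vcf --groups groups.tsv

# the standard filter cascade (invariant and SNP records filtered separately)
relictpop filter --vcf cohort.vcf --out combined.vcf

# windowed statistics
relictpop diversity --vcf combined.vcf --groups groups.tsv --stat pi --window 10000
relictpop diversity --vcf combined.vcf --groups groups.tsv --stat fst \
    --group MK --group2 wild
relictpop ld --vcf combined.vcf --groups groups.tsv --group MK --downsample 10
relictpop prune --vcf combined.vcf --indep-pairwise 50 10 0.1 --out-prefix pruned
relictpop structure --vcf combined.vcf --pca 20 --out-prefix struct
relictpop neutrality --vcf combined.vcf --groups groups.tsv --group MK \
    --win 50000 --step 10000 --out-prefix mk
relictpop novel --vcf combined.vcf --groups groups.tsv --out-prefix novel

# or everything at once from a flat key=value config
printf 'out_dir=run\nvcf=cohort.vcf\ngroups=groups.tsv\n' > run.cfg
relictpop run --config run.cfg
```

## Conventions

- VCF positions are 1-based; BED intervals are 0-based half-open.
- Dosages are alternate-allele counts in {0, 1, 2} with −1 for missing;
  half-calls count as missing.
- MAC/MAF are computed over called genotypes only.
- Windows are anchored at position 1 and half-open; undefined windows carry
  NaN (never 0) and are excluded from window means. Summaries report both
  pooled (ratio-of-sums) and window-mean variants.
- Sites without a known mean depth pass the depth filter (logged).
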