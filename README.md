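# phasecn

Sequential Monte Carlo haplotype phasing for joint CNV/SNP genotype data.

Each locus of an individual is observed as a pair `total_cn:allele1_count`
(total copy number 0–4 across both chromosomes, and how many of those copies
carry allele 1). `phasecn` infers, per chromosome, the allele content at every
locus — symbols `-` (deleted), `0`, `1` (single copy), `00`, `01`, `11`
(duplicated) — and estimates population haplotype frequencies.

## Method

* **Enumeration** — for each individual all haplotype assignments consistent
  with the observed genotype are enumerated (blocks of ≤ 5 loci).
* **Sequential sampler** — individuals are processed one at a time. The
  algorithm keeps `K` candidate solution streams (*particles*); each is
  expanded with every compatible assignment of the next individual, weighted
  by the Dirichlet-multinomial predictive probability of the new haplotype
  draws given the stream's accumulated counts (a multivariate beta-function
  ratio, computed in log space), and the top `K` children are retained
  deterministically.
* **Partition-ligation** — longer marker sets are split into blocks of 5
  loci; neighboring block solutions are merged by pairing chromosomes so the
  junction copy-number changes are minimal (both pairings when tied), and the
  sampler is rerun over merged candidates with weights offset by the product
  of the source solution weights.
* **Internal phasing** — inside a duplicated chromosome run, the two copies
  are resolved by mapping the run to an equivalent two-copy phasing problem,
  pooled across chromosomes and anchored by the resolved single-copy
  segments of the rest of the sample (`ligation.internal_refine`).
* **Simulator** — generates datasets with known truth: an LD-bearing phased
  SNP panel from a mosaic founder-copying model, MAF ≥ 5% filter, and
  sequential CNV insertion into frequency-selected haplotypes (start
  probability 0.1 per position, lengths uniform on 3–8 loci, deletions or
  duplications with tandem / resampled / donor-haplotype content).
* **Evaluation** — ambiguity-restricted switch error rate with a by-CN 2×2
  junction table, internal (duplicated-region) switch error, and χ² / l₁
  distances between estimated and gold-standard haplotype frequencies.

## Command line

```sh
# simulate a dataset with known truth
phasecn simulate -L 30 -T 88 --seed 7 --outdir data/

# phase it
phasecn phase data/genotypes.tsv -K 50 --outdir run/

# score the result
phasecn evaluate data/truth.tsv run/phased.tsv \
    --genotype-file data/genotypes.tsv \
    --gold-frequencies data/gold_frequencies.tsv \
    --predicted-frequencies run/frequencies.tsv

# empirical haplotype frequencies of any haplotype TSV
phasecn frequencies data/truth.tsv --out data/empirical.tsv
```

File formats are plain TSV: genotypes as `cn:count` cells, haplotypes as two
symbol rows per individual, frequencies as `haplotype<TAB>frequency`.

## Python API

```python
from phasecn import SimConfig, simulate, hierarchical_phase, switch_error_rate

truth = simulate(SimConfig(L=30, T=88, seed=1))
result = hierarchical_phase(truth.genotypes, K=50)
report = switch_error_rate(truth.genotypes, truth.assignments, result.assignments)
print(report.rate, report.table())
```

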