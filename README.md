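# rohkit

Runs-of-homozygosity (ROH) profiling toolkit for whole-genome SNP genotype
data. It bundles, in one tested pipeline:

- **cohort simulation** (`rohkit.cohortsim`) — synthetic cohorts with known
  planted autozygous segments (short ≥100 Kb and long >1.5 Mb regimes),
  Hardy–Weinberg founders, three-generation pedigrees (trio/septet/octet
  templates) transmitted under the Haldane recombination model, spurious
  heterozygote errors at a configurable per-Mb rate, systematic "bad sites"
  that produce Mendelian inconsistencies, and array-density site masks;
- **format I/O** (`rohkit.genomic_io`) — multi-sample VCF (read/write, GT
  codes 0/1/2/−1), PLINK FAM pedigrees, BED/GFF3 intervals, and 3-column
  genetic-map TSVs with linear cM interpolation;
- **site filtering** (`rohkit.site_filter`) — biallelic-SNP / allele
  frequency (0.05–0.95, inclusive) / missingness filters and
  centromere-aware chromosome-arm splitting;
- **two ROH callers** — a two-state autozygosity HMM with Viterbi decoding,
  genetic-map–scaled exponential transitions, and a phred-scaled genotype
  error channel (default 30, i.e. 1e-3) (`rohkit.roh_hmm`); and a
  sliding-window homozygosity scanner with a tunable per-window heterozygote
  allowance (`rohkit.roh_window`);
- **profiling** (`rohkit.roh_profile`) — per-individual NROH/SROH by minimal
  length class (100 Kb / 300 Kb / 1.5 Mb), length-interval histograms, and
  the F_ROH genomic inbreeding coefficient;
- **ROH islands** (`rohkit.islands`) — per-site cross-individual overlap
  counts, nearest-rank percentile thresholds (99.9th/99.5th), interval
  merging, and gene-overlap annotation;
- **pedigree QC** (`rohkit.pedigree_qc`) — Mendelian trio checks, recurrent
  error-site flagging, and site removal;
- **experiments** (`rohkit.experiments`) — all-sites vs array-trimmed
  comparisons, heterozygote-allowance sweeps, density-matched pruning with
  iteration averaging, and Mendelian-filtered reruns.

## CLI

The `rohkit` entry point chains the pipeline stages:

```sh
rohkit simulate --config sim.yaml --out run/          # VCF + FAM + map + truth/mask BEDs
rohkit filter --vcf run/cohort.vcf --out run/filtered.vcf --exclude-bed centromeres.bed
rohkit call-hmm --vcf run/filtered.vcf --map run/genetic_map.tsv --out run/hmm
rohkit call-window --vcf run/filtered.vcf --out run/win --sweep
rohkit profile --segments run/hmm.tsv --out run/profile.tsv --autosome-length-bp 40000000
rohkit islands --segments run/hmm.tsv --vcf run/filtered.vcf --percentile 99.9 \
    --genes genes.gff3 --out run/isl
rohkit mendel --vcf run/cohort.vcf --fam run/cohort.fam --out run/qc --write-filtered-vcf
rohkit prune --vcf run/filtered.vcf --target 2000 --iterations 10 --seed 1 --out run/prune
rohkit report --vcf run/cohort.vcf --callers hmm,window --het-values 1,2,3,4 --out run/tables
```

A minimal simulation config:

```yaml
chrom_lengths: {chr1: 40000000}
seed: 1
n_founders: 20
pedigree_spec: {septet: 4}
site_density: 100.0          # sites per Mb
af_law: [1.0, 1.0]           # Beta shape parameters for alt allele frequency
het_error_rate: 4.5          # spurious hets per Mb per sample
bad_site_fraction: 0.02
bad_site_error_prob: 0.25
array_mask_fraction: 0.25
planted_segments:
  - {count: 2, law: uniform, min_bp: 300000, max_bp: 1400000}
  - {count: 1, law: uniform, min_bp: 1600000, max_bp: 3000000}
```

## Conventions

- Coordinates are 1-based inclusive internally; BED conversion happens only
  at I/O boundaries. Genotypes are unphased dosage codes (0 hom-ref, 1 het,
  2 hom-alt, −1 missing).
- Genetic maps are 3-column TSVs (chrom, pos, cumulative cM; header
  optional, auto-detected). Positions beyond the last anchor extrapolate at
  a configurable constant rate (default 1 cM/Mb).
- Allele frequencies are cohort-internal (recomputed from non-missing calls
  when INFO/AF is absent).
- All randomness flows through `numpy.random.default_rng(seed)`; fixed
  seeds reproduce every output bit-for-bit.

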