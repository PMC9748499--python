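# graftmobile

Exact Bayesian detection of graft-mobile transcripts from per-SNP RNA-Seq
read counts.

When two plants with different genotypes are grafted, transcripts found in
one tissue that carry SNP alleles of the *other* genotype may have crossed
the graft junction — or they may be sequencing/mapping errors. `graftmobile`
decides between the two analytically:

1. **Error model.** For each SNP, homograft (same-genotype graft) counts give
   a conjugate Beta posterior over that SNP's error rate: a flat
   `Beta(u1, u2)` prior updated with the observed distal-matching reads.
   Replicates pool exactly; splitting the data changes nothing.
2. **Mobile-read posterior.** For a heterograft SNP with `N` reads of which
   `n` match the distal genotype, the discrete posterior `P(N2 | D)` over the
   number of genuinely distal reads `N2 ∈ {0..N}` is computed in closed form
   (beta-binomial convolution, uniform prior over `N2`). Its expectation
   `⟨N2⟩` and ratio `r2 = ⟨N2⟩/N` quantify transport.
3. **Evidence.** The per-SNP log10 Bayes factor is
   `log10(max_{N2>0} P(N2|D) / P(N2=0|D))`; contributions from all SNPs and
   replicates of a transcript add. A transcript is labelled *mobile* when the
   total reaches the threshold (default `log10 BF ≥ 1`).

Two error models are available: the default **two-rate** model (genuinely
distal reads can themselves be misread, using the distal genotype's homograft
posterior) and a **single-rate** simplification (distal reads always observed
as distal), used automatically when no distal homograft table is supplied.

The package also ships the threshold baselines **Method A** (distal reads
`> 3` in 2 of 3 replicates) and **Method B** (Method A after discarding every
SNP with any homograft distal reads), a binomial read-count simulator, a
blending generator that titrates one count table into another at proportion
`p`, and evaluation sweeps (accuracy/TPR/FPR vs read depth and SNP count).

## Count-table schema

Tab-separated (comma auto-detected), `#` comment lines for provenance,
one row per (transcript, SNP, replicate):

| column | meaning |
|---|---|
| `transcript_id` | opaque transcript key |
| `snp_id` | opaque SNP key (no genomic interpretation) |
| `replicate_id` | opaque replicate key |
| `tissue` | `scion` or `stock` (used to pair heterograft with homograft) |
| `genotype_sampled` | genotype of the sampled tissue |
| `total_reads` | `N ≥ 0` |
| `distal_reads` | `n`, reads matching the distal genotype, `0 ≤ n ≤ N` |

Extra columns ride along untouched. A conformance fixture lives at
[`examples/counts_conformance.tsv`](examples/counts_conformance.tsv).
Duplicate `(transcript_id, snp_id, replicate_id)` keys, non-integer counts
and `n > N` are hard errors with row numbers reported.

## CLI

```sh
# simulate a balanced labelled cohort
graftmobile simulate --n-transcripts 100 --error-rate 0.01 \
    --heterograft-depth 1000 --homograft-depth 1000 --mobile-reads 50 \
    --seed 1 --out-dir data/

# score transcripts with Bayes factors
graftmobile infer --heterograft data/heterograft.tsv \
    --local-homograft data/homograft_local.tsv \
    --distal-homograft data/homograft_distal.tsv \
    --threshold 1.0 --out scores.tsv

# threshold baselines
graftmobile baseline --method a --heterograft data/heterograft.tsv --out a.tsv
graftmobile baseline --method b --heterograft data/heterograft.tsv \
    --homograft data/homograft_local.tsv --out b.tsv

# blend two homograft tables into labelled pseudo-heterograft data
graftmobile blend --local col0.tsv --distal ped0.tsv -p 0.1 --out-dir blended/

# compare predictions against truth labels
graftmobile evaluate --truth data/labels.tsv --predictions scores.tsv \
    --out metrics.tsv
```

Every command accepts `--seed`, writes a `run.log`/`.log` file with the
resolved configuration, and exits non-zero on validation failures.
`simulate` also accepts `--config file.yaml` (flat key–value; CLI flags win).

## Python API

```python
from graftmobile import (
    SnpCounts, fit_error_posterior, posterior_over_n2, snp_log_bf,
    transcript_log_bf, classify_heterograft,
)

post = fit_error_posterior([SnpCounts("s1", "r1", 10_000, 100)])
mobile = posterior_over_n2(SnpCounts("s1", "r1", 1000, 60), post)
mobile.expected_n2      # ~50.4
snp_log_bf(mobile)      # strongly positive
```

`classify_heterograft(het, local_hom, distal_hom)` runs the whole pipeline on
data frames and returns per-transcript and per-SNP result tables.
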