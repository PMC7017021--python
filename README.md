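# cubdfe

Inference of purifying selection on synonymous sites from population
polymorphism data, using matched short-intron neutral controls and a
categorical distribution-of-fitness-effects (DFE) maximum-likelihood
estimator on folded site frequency spectra.

## What it does

* **Neutral-control construction** — identifies fourfold-degenerate (4D)
  codon sites and short-intron (SI) sites from a genome + GFF3, applies
  quality/indel/multiallelic filters, downsamples to a uniform haplotype
  count, polarizes alleles by outgroup parsimony, and pairs every 4D site
  with an SI site on the same chromosome within 1 kb carrying the same
  ancestral allele and 3-bp context up to strand-blind transforms
  (forward / reverse / complement / reverse complement). 200 independent
  random assignments form the replicate control sets.
* **Categorical-DFE likelihood** — a multinomial likelihood over
  {monomorphic, folded frequency classes} for the 4D spectrum under a
  mixture of neutral, selected (gamma = Ne·s) and lethal site classes,
  times the SI spectrum under neutrality, sharing theta and per-frequency-
  bin demographic correction factors (alpha). Five nested models
  (`n`, `n+l`, `n+s`, `n+s+l`, `n+s+s`) are fitted by multi-start
  Nelder-Mead (with a faster profile-likelihood variant that exploits
  concavity in the class weights), compared by chi-squared LRT, and given
  95% rank-bootstrap confidence intervals.
* **Summaries** — RSCU and per-family preferred codons, per-gene FOP with
  quartile groups, the polymorphism ratio log(P_SI/P_4D) per stratum and
  per codon change, strong-selection site counts, ribosomal occupancy
  scores and sliding-window score correlations.
* **Synthetic data** — a Wright-Fisher equilibrium simulator producing
  expected/sampled folded spectra and full site tables (FASTA + GFF3 +
  BED + TSV fixtures) with preference-dependent DFEs, context-dependent
  mutation rates and a regional theta gradient, so the entire pipeline is
  testable without any external downloads.

## CLI

```sh
cubdfe simulate --scale tiny --seed 1 --out fixtures/      # synthetic dataset
cubdfe annotate --genome genome.fa --annotation genes.gff3 --out sites.tsv
cubdfe match    --sites sites.tsv --replicates 200 --max-dist 1000 --seed 1 --out matched/
cubdfe fit      --sfs-4d sfs4d.tsv --sfs-si sfssi.tsv --ne 2000 --boundary -10 --out fit.json
cubdfe summarize --sites sites.tsv --out summaries/
cubdfe run      --config config.yaml --out run/             # full pipeline
```

A pipeline configuration is a single YAML file; the important knobs
(Ne = 2000, 160 haplotypes, 200 replicates, 1000 bp matching distance,
intron length rule > 86 bp with 8 bp trimmed ends, MAPQ 20, 10 bp indel
window, weak/strong boundary at Ne·s = −10) all live in it. Example:

```yaml
seed: 1
population: {ne: 2000, ns: 160}
matching: {n_replicates: 200, max_dist: 1000}
fit: {models: [n, n+l, n+s, n+s+l, n+s+s], boundary: 10.0, replicates: 1}
synthetic:
  n_genes: 250
  theta: 0.035
  dfe_preferred: [[-1.0, 0.2], [-30.0, 0.1]]
```

Replace the `synthetic` block with an `inputs` block
(`genome` / `annotation` / `sites` / `indels` paths) to run on real data;
the per-site allele table is a TSV with columns chrom, pos, site_class,
ancestral, derived, derived_count, n_haplotypes, context3, gene_id,
codon, strand.

## Layout

```
src/cubdfe/
  spectra.py              core Wright-Fisher spectrum machinery
  synthetic_data.py       spectrum- and site-level simulators
  site_matching.py        annotation, filters, polarization, matching
  dfe_likelihood.py       alpha fitting, joint likelihood, nested models
  selection_summaries.py  RSCU/FOP, polymorphism ratios, correlations
  pipeline.py, cli.py     orchestration and the `cubdfe` entry point
```
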