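# germpop

Population-genomic characterization toolkit for inbred (highly selfing)
germplasm SNP panels, built around dosage-coded biallelic genotype
matrices (DArT-style wide tables or VCF).

The pipeline covers:

* **genotype_io** — wide-table (one-row dosage and two-row
  presence/absence dialects), VCF 4.2 read/write, sample/genome-map
  tables, per-marker QC (call rate, MAF, PIC, het rate) and threshold
  filtering.
* **simulate** — synthetic germplasm collections with two diverged gene
  pools (Balding–Nichols model, calibrated by bisection so the realized
  Nei FST hits the configured target), landrace/cultivar strata, strong
  selfing, admixed accessions, block-structured LD from recombined
  founder lineages, loci under divergent selection, missing data and
  clustered geo-coordinates — with full ground truth for recovery tests.
* **diversity** — per-group Ho/He/uHe/F, percent polymorphic, private
  alleles, probability of identity and one-parent exclusion power, and
  hierarchical Nei-style FST/FIS/FIT (Weir–Cockerham theta as an
  option).
* **genome_scan** — non-overlapping 100-kb windows: segregating sites,
  Watterson's theta, pi, Tajima's D, Hudson/Nei window FST.
* **outlier_scan** — FDIST-style hierarchical-island simulation envelope
  (heterozygosity-conditioned empirical p-values) and a spike-and-slab
  Bayesian logistic-FST sampler (posterior inclusion probabilities and
  q-values); call intersection across methods/runs.
* **linkage** — Yang/GCTA genetic relationship matrix, pairwise dosage
  r², structure/kinship-corrected r²_SV (kinship whitening + covariate
  projection), nonlinear LD-decay fitting with half-decay distance,
  deterministic LD pruning, and evenly spaced SNP-panel selection.
* **hapblocks** — two-locus haplotype frequencies (het-as-missing or
  EM), D′ likelihood-grid confidence intervals, confidence-interval
  haplotype blocks and per-chromosome summaries.
* **structure_lite** — EM admixture estimation (Q matrix, q ≥ 0.7
  assignment), simple-matching distances, neighbor-joining trees with
  locus-bootstrap support (newick output), and 150-km-neighborhood
  spatial He grids.
* **pipeline / cli** — one-config orchestration with per-stage CSV
  artifacts and JSON provenance.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact
summary-layer arithmetic, and property-based checks with independent
oracles: simulator FST recovery, the Nei decomposition identity, neutral
Tajima's D, FDIST type-I error, Bayesian outlier power/null calibration,
r²_SV reduction/deflation, decay-parameter recovery, block recovery, and
brute-force equality of every core statistic). One test replicates
numbers from the study's supplementary genotype table and is skipped
unless that file is available locally (`GERMPOP_SUPP_GENOTYPES`).

## CLI

```bash
germpop simulate --seed 1 --n-markers 2000 --out-dir sim_out
germpop qc sim_out/genotypes.csv --out qc.csv
germpop diversity sim_out/genotypes.csv sim_out/samples.csv --out div.csv
germpop scan sim_out/genotypes.csv sim_out/samples.csv sim_out/genome_map.csv
germpop outliers sim_out/genotypes.csv sim_out/samples.csv --method both
germpop ld sim_out/genotypes.csv --corrected
germpop blocks sim_out/genotypes.csv
germpop panel sim_out/genotypes.csv sim_out/samples.csv --size 560
germpop structure sim_out/genotypes.csv --k 2
germpop tree sim_out/genotypes.csv --bootstrap 100
germpop spatial sim_out/genotypes.csv sim_out/samples.csv
germpop run-all config.yaml
```

`run-all` reads a flat YAML config (see `germpop.pipeline.PipelineConfig`
for keys and defaults) and writes every stage artifact plus
`provenance.json` into the configured output directory.

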