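# f2map

Construction of ultra-dense F2 bin maps from whole-genome resequencing
genotype calls, and mapping of a monogenic recessive trait — implemented
as a tested, reusable pipeline exercised end-to-end on synthetic data.

The pipeline covers:

1. **simcross** — synthetic data generator: two homozygous founders
   differing at parent-unique SNP loci, F2 progeny built from two
   independently recombined gametes, Poisson read depth with per-read
   error and missing calls, a fully penetrant recessive trait locus
   (3:1 segregation) and an optional hemizygous deletion.
2. **variants** — per-sample VCF merging, the high-quality presence
   filter (call count within `[min_calls, max_calls]` across progeny and
   parents), and parent-unique homozygous SNP classification.
3. **genotyping** — six-symbol coding ({AA, BB, H, C, D, −}; AA/BB
   require depth ≥ 5, low-depth homozygotes become D/C) and a
   forward–backward HMM along each scaffold that posterior-decodes the
   low-confidence symbols and removes isolated miscalls.
4. **binmap** — collapsing identical adjacent genotype vectors into
   recombination bins, 1:2:1 chi-square distortion filtering, two-point
   recombination fractions by EM, linkage grouping (LOD ≥ 8, r ≤ 0.35),
   weighted least-squares bin ordering and Kosambi cM positions with
   per-LG summary statistics.
5. **traitmap** — Yates-corrected segregation tests, a penetrance-
   likelihood genome scan with R² and 1-LOD support intervals,
   permutation LOD thresholds, co-segregation coefficients and physical
   interval arithmetic.
6. **structvar** — zero-coverage run detection for genomic deletions,
   amplicon presence/absence prediction and gene loss/truncation reports.
7. **cli** — one YAML-configured, seed-reproducible pipeline.

## Command line

```sh
# full simulated run with default parameters
f2map all --seed 1 --out runs/demo

# individual stages (each re-runs the deterministic pipeline up to
# that stage and writes its artifacts)
f2map simulate --config config.yaml --seed 1
f2map map --config config.yaml
f2map scan --config config.yaml
f2map sv --config config.yaml
```

A config file is a flat YAML mapping of `f2map.cli.PipelineConfig`
fields, e.g.

```yaml
n_progeny: 120
scaffolds:
  - {name: sc01, length_bp: 1000000, length_cm: 60.0}
snp_density: 2.0e-4
mean_depth: 10.0
depth_threshold: 5
min_lod: 8.0
max_rf: 0.35
n_perm: 1000
out_dir: runs/demo
```

Artifacts (per-sample VCFs, genotype matrices, bin map, scan table,
deletion calls, `report.json`) are written under `out_dir`. Exit code 2
signals a configuration error, 1 a stage failure.

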