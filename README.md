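# bsamap

Bulked-segregant association mapping for F2 populations, built around
pool-sequencing allele depths:

- **SNP filtering** — depth, parental-polymorphism, multiallelic and
  between-pool-monomorphism screens with deterministic removal counters.
- **Association statistics** — per-SNP SNP-index (per bulk, plus the
  between-bulk delta) and the Euclidean distance of within-bulk base
  frequencies, raised to the 5th power to sharpen peaks.
- **Smoothing** — 200-SNP sliding-window means and local linear (loess)
  regression with tricube weights, the span chosen per chromosome by
  minimising the corrected AIC (AICc).
- **Region calling** — explicit or median + k·SD thresholds, maximal
  above-threshold runs, and intersection of the two methods' regions.
- **Fine mapping** — recombinant counting on the homozygous-recessive F2
  class (0/0, 0/1, 1/1 coding), interval delimitation by flanking
  recombinant markers, Kosambi map-distance conversion, and a 3:1
  segregation chi-square check.
- **Synthetic data** — an F2 bulk-sequencing simulator (crossover process
  without interference, phenotype bulking, Poisson/multinomial read depths
  with sequencing error) so the whole pipeline is testable end to end.

## Command line

Every stage is a subcommand; intermediate TSV/BED files are the contract
between stages:

```bash
bsamap simulate --config sim.yaml --out depths.tsv           # synthetic data
bsamap filter --input depths.tsv --out filtered.tsv --min-bulk-depth 5
bsamap associate --input filtered.tsv --out assoc.tsv --window-n 200
bsamap regions --assoc assoc.tsv --stat loess_ed5 --threshold 0.15 --out ed.bed
bsamap regions --assoc assoc.tsv --stat loess_delta --threshold 0.26 --out delta.bed
bsamap intersect --a ed.bed --b delta.bed --out candidate.bed
bsamap finemap --genotypes genotypes.tsv --population-size 172
bsamap run --input depths.tsv --out-dir out/                 # whole pipeline
```

Exit codes: 0 ok, 1 data error, 2 configuration error.

The canonical depth table is a TSV with columns
`chrom pos ref alt p1_allele p2_allele dom_A dom_C dom_G dom_T rec_A rec_C
rec_G rec_T p1_depth p2_depth`; a 4-sample VCF with AD annotations can be
read with `bsamap.io.read_vcf_bulks`. Coordinates are 1-based inclusive
internally and converted to BED convention only on output.

## Python API

```python
import bsamap

ds = bsamap.simulate_dataset(seed=1)                    # synthetic F2 bulks
summary = bsamap.run_pipeline(bsamap.PipelineConfig(out_dir="out"),
                              sites=ds.sites)
print(summary.regions["intersection"])
```

## Notes

- The depth filter default is 5 reads per bulk (the SNP-calling-stage
  cutoff); a 4-read variant of the rule can be selected with
  `--min-bulk-depth 4`, and `--either-pool` relaxes the two-pool
  requirement.
- The ED statistic uses within-bulk base *frequencies* (bounded by √2);
  a raw-depth mode is available via `ed_mode="raw"` for completeness.
- Undefined statistics (zero usable depth) propagate as missing and are
  excluded from smoothing and thresholds, never imputed as 0.
- Sites on placeholder chromosomes ("chrUn", "unknown") keep per-SNP
  statistics but are excluded from windows, loess and region calling.
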