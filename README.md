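# kinoscope

Subcellular kinome profiling from multi-exposure peptide-array kinetics.

The pipeline starts at quantified intensity tables from a serine/threonine
reporter-peptide chip (peptide × group × chip × exposure time → intensity)
and runs:

1. **Slope signals** — per-well OLS slope of intensity vs. camera exposure
   time (the kinase-activity readout), with linearity (R²) diagnostics.
2. **QC** — drop peptides with very low signal at the largest exposure
   (default < 2 at 200 ms) or non-linear kinetics (default R² < 0.9).
3. **Normalization** — log2 signal matrix plus a per-peptide Z-scaled copy.
4. **Differential phosphorylation** — within-chip log2 fold-changes between
   two groups, averaged across replicate chips, classified against a ±0.15
   cutoff; chip-to-chip CV report; Wilcoxon rank-sum / signed-rank global
   tests.
5. **Upstream kinase enrichment** — a random-resampling score per kinase:
   Z = (observed differential hits − resampling mean) / resampling sd, with
   draws taken without replacement from the QC-passed peptide universe.
6. **Harmonization** — percentile-rank normalization (rank/N, average ties,
   best = 1.0, lower-is-better scores inverted) of any number of kinase
   ranking tools, combined by mean/median percentile; a kinase is *selected*
   when reported by ≥ 2 tools with mean percentile ≥ 0.75; overlap sets
   between comparisons.
7. **Reporting** — clustered Z-score heatmaps, log2FC waterfalls,
   violin/box global-signal plots, kinetic curves, and a run manifest with
   file digests. Every figure also writes its underlying table.

A fully ground-truthed synthetic data generator (144 peptides, 4 groups,
3 chips, 5 exposure times, linear kinetics, group-specific kinase activity,
multiplicative log-normal noise) makes every stage testable offline.

## CLI

```sh
# synthetic dataset with two elevated kinases in the synaptosomal group
kinoscope simulate --config config.yaml --out-dir run/ --seed 1

# slopes, QC, normalized matrices
kinoscope preprocess --signals run/signals.tsv --design run/design.tsv \
    --low-signal 2 --min-r2 0.9 --out-dir run/

# within-chip differential comparison
kinoscope diff --slopes run/slopes.tsv --case synaptosomal --control nuclear \
    --cutoff 0.15 --out-dir run/

# resampling kinase enrichment (seed required for reproducibility)
kinoscope krsa --log2fc run/log2fc.tsv --map run/kinase_map.tsv \
    --cutoff 0.15 --iterations 2000 --seed 42 --out run/krsa_results.tsv

# harmonize with external tool rankings (UKA scores, KEA3 ranks, ...)
kinoscope harmonize --krsa run/krsa_results.tsv --tool uka:uka.tsv \
    --tool kea3:kea3.tsv --aliases aliases.tsv \
    --min-tools 2 --min-mean 0.75 --out run/harmonized.tsv

# regenerate figures + markdown summary
kinoscope report --run-dir run/
```

A `config.yaml` for `simulate` mirrors `SimulationConfig`, e.g.:

```yaml
n_peptides: 144
n_kinases: 16
peptides_per_kinase: [8, 16]
groups: [nuclear, cytosolic, synaptosomal, total]
n_chips: 3
exposure_times: [10, 20, 50, 100, 200]
active_kinases:
  synaptosomal: {KIN01: 1.5, KIN02: 1.5}
baseline_slope: 1.0
noise_cv: 0.05
seed: 1
```

All tables are TSV with a header row; external tool scores carry an explicit
`score_direction` column (`higher_is_better` / `lower_is_better`) so rank
files cannot be silently inverted.

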