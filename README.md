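# glycoscreen

A tested Python implementation of a serum glycopeptide LC-MS screening
pipeline: peak-table processing, glycopeptide mass assignment, biomarker
screening, tiered machine-learning models and prevalence-adjusted screening
evaluation — driven end-to-end by a synthetic-cohort simulator with known
ground truth.

## Modules

| module | role |
| --- | --- |
| `glycoscreen.synthdata` | synthetic four-group cohorts (healthy, CRC, GC, EC) with stage structure, log-normal tumor-marker panels, and long-format peak tables with planted species, isotope/adduct/fragment satellites, noise peaks, detection dropout and coordinate jitter |
| `glycoscreen.peaks` | greedy seeded peak alignment (0.06 Da / 0.3 min tolerances), three-step feature selection (QC CV > 50 %, S/N < 5, satellite ions) and QC-ratio normalization |
| `glycoscreen.glycoid` | in-silico digestion (cleave after K/R, not before P), N-sequon filtering, glycan-composition enumeration and negative-mode neutral-mass assignment within 0.03 Da; anchor-protein (transferrin-style) normalization |
| `glycoscreen.biomarkers` | equal-variance t-tests with zero imputation, mean-fold ratios, volcano labels (p < 1e-10, MFR beyond 2^±0.5) and the candidate screen (p < 1e-10, fold change beyond 1.5x, intra/inter-day CV ≤ 15 %) |
| `glycoscreen.classify` | Model 1 (nine markers) / Model 2 (+ two sentinel glycopeptides) / Model 3 (+ 100 PCA components of the glycopeptide block, fitted per training split), neural-net or gradient-boosting back ends, repeated stratified 70/30 splits with pooled held-out ROC |
| `glycoscreen.screen_eval` | capped -log10(1 - p) score, cutoff classification (default 5), prevalence-adjusted PPV/NPV on a 100,000 population, stagewise ROC and the two-stage detect-then-type classifier |

## CLI

```bash
glycoscreen simulate --config config.yaml --out simdir --seed 7
glycoscreen align   --peaks simdir/peaks_samples.csv --out features.csv
glycoscreen filter  --peaks simdir/peaks_samples.csv \
                    --qc-intra simdir/peaks_qc_intra.csv \
                    --qc-inter simdir/peaks_qc_inter.csv --out filtered/
glycoscreen assign  --fasta proteins.fasta --features features.csv --out hits.csv
glycoscreen screen  --matrix egp_matrix.csv --subjects simdir/subjects.csv \
                    --group GC --out stats.csv
glycoscreen train   --subjects simdir/subjects.csv --model 1 --algo gbt \
                    --out pooled.csv
glycoscreen evaluate --predictions pooled.csv --prevalence 99 --cutoff 5
```

`simulate` accepts a YAML file whose keys mirror
`glycoscreen.synthdata.CohortConfig` (group sizes, stage weights, planted
effect sizes, satellite rates, detection limit, jitter, QC replicate CVs...).

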