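# nirspipe

Analysis pipeline for block-design fNIRS recordings with suppression of
systemic physiological interference. The chain per channel is:

1. **MBLL** (optional): optical-density changes at three wavelengths →
   pathlength-scaled HbO₂/HbR/HbT via least squares.
2. **Preprocessing**: median filter (window 3) → 2nd-order polynomial
   detrend → Z-score (cancels the unknown per-channel pathlength factor)
   → zero-phase 2nd-order Butterworth low-pass at 0.08 Hz.
3. **Task-unrelated regression**: channels whose Pearson correlation
   with the raw task boxcar satisfies |r| < 0.2 are averaged into one
   regressor per hemisphere, which is regressed out (OLS) of every
   channel on that hemisphere only.
4. **GLM**: one HRF-convolved boxcar column per trial; OLS gives one β
   per trial; per-condition activation = mean of trial βs.
5. **Group statistics**: per-channel one-sample t-tests with
   Benjamini-Hochberg FDR maps; ROI means; 2×2 repeated-measures ANOVA
   (task × hand) with partial η²; Bonferroni-corrected paired post hocs.

A synthetic-data module generates 31-channel group datasets (7.14 Hz,
10 s task / 15 s rest blocks) with known ground truth: HRF responses in
designated channels, globally shared cardiac / respiratory / Mayer-wave /
very-low-frequency components, optional task-locked systemic responses,
polynomial drift, white noise, and per-channel pathlength factors — so
every downstream stage is testable without any external data.

## CLI

```sh
nirspipe simulate --scenario contralateral-M1 --n-subjects 16 --out-dir sim/
nirspipe preprocess sim/S01_ME_left.tsv pre.tsv
nirspipe regress pre.tsv clean.tsv --figure corr.png
nirspipe glm clean.tsv --out betas.tsv
nirspipe group betas.tsv --out-dir group/
nirspipe all --seed 1 --out-dir out/        # full chain, all 4 conditions
```

Recordings are commented TSV (`# subject/condition/species/fs` header,
then `time` plus one column per channel). `nirspipe all` accepts a YAML
config (`--config`) covering every stage parameter and writes a manifest
with the config hash and seed; identical config + seed reproduces every
artifact bit-for-bit.

## Layout

- `src/nirspipe/probe_geometry.py` — optode grid, channel enumeration, ROI labels
- `src/nirspipe/synthetic_data.py` — task designs, systemic interference, group simulation
- `src/nirspipe/mbll.py` — modified Beer-Lambert conversion
- `src/nirspipe/preprocess.py` — median / detrend / Z-score / low-pass chain
- `src/nirspipe/systemic_regression.py` — hemispheric task-unrelated regression
- `src/nirspipe/glm_activation.py` — trial-wise GLM and β tables
- `src/nirspipe/group_stats.py` — t-maps, FDR, repeated-measures ANOVA, post hocs
- `src/nirspipe/cli_io.py` — file formats, pipeline config, CLI
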