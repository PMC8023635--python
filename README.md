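# comanet

Resting-state EEG features and prognosis for acute post-traumatic
unresponsive states.

After a severe traumatic brain injury, patients who do not follow commands
once sedation is withdrawn pose the hardest prognostic question in the
intensive care unit. Standard clinical EEG (19 electrodes, a few minutes of
resting-state data) carries candidate prognostic signals: the power of the
alpha (8–13 Hz) and delta (0.5–4 Hz) rhythms, the strength of phase-lagged
functional connectivity, and graph-theoretic summaries of the connectivity
network. `comanet` implements that analysis chain as a reusable, tested
Python library, together with synthetic EEG and synthetic cohorts so that
every stage can be validated end-to-end without clinical data.

## What it computes

For each recording, after preprocessing (0.5–45 Hz zero-phase band-pass,
10-s epochs, deterministic artifact rejection, average reference), eight
scalar features:

| feature | definition |
| --- | --- |
| `alpha_rel_power`, `delta_rel_power` | mean over channels of band power / total 0.5–45 Hz power |
| `alpha_median_dwpli`, `delta_median_dwpli` | median over channel pairs of the debiased weighted phase lag index |
| `alpha_modular_span` | mean weight-weighted electrode distance covered by a network module (head-radius units) |
| `alpha_participation_sd` | SD over channels of the participation coefficient P_i = 1 − Σ_m (κ_im/κ_i)² |
| `delta_clustering_mean` | mean Onnela weighted clustering coefficient |
| `delta_modularity` | Newman modularity Q of the best Louvain partition |

Graph metrics are computed on proportionally thresholded weighted graphs and
averaged over connection densities 90–10 %. The dwPLI estimator, built from
the imaginary cross-spectrum only, is insensitive to the zero-lag coupling
produced by volume conduction:

    dwPLI = ((Σ I_k)² − Σ I_k²) / ((Σ |I_k|)² − Σ I_k²),   I_k = Im(Z_k)

Inference tools: canonical correlation analysis between the clinical picture
and the EEG features with a 2000-permutation max-statistic randomization
test; rank-based inverse-normal (Blom) transformation of GOSE outcomes; and
stepwise linear regression (entry p = 0.05, removal p = 0.10) with
standardized betas, adjusted R² and R²-change reporting. A cross-montage
validation procedure screens which features can be estimated reliably from
19 channels by comparing against a 91-channel processing path on healthy
subjects.

## Worked example

The numbered drivers under `analysis/` run the full analysis pipeline on a
synthetic 18-patient cohort (5-minute, 19-channel EEG each, outcome driven
by GCS and the latent alpha level):

```bash
python analysis/01_simulate_cohort.py --seed 1   # EDFs + cohort.csv
python analysis/02_extract_features.py --seed 1  # the 8 features per patient
python analysis/03_validate_montage.py --seed 1  # 91- vs 19-channel reliability
python analysis/04_cca.py --seed 1               # clinical vs EEG CCA
python analysis/05_prognosis.py                  # stepwise GOSE models
```

With seed 1 this prints (abridged):

```
canonical pair 1: r = 0.910, permutation p = 0.0445
canonical pair 2: r = 0.722, permutation p = 0.7670

gose_6mo: gcs_total (beta=0.6073, p=0.0008), alpha_rel_power (beta=0.4544,
p=0.0069); adjusted R^2 = 0.6603; R^2 change vs GCS alone = 0.1959
```

Read: the first pair of canonical variates links the clinical picture to
the EEG feature set (r = 0.91) and survives the max-statistic permutation
test (p = 0.044); and the 6-month outcome model keeps total GCS plus mean
relative alpha power, with alpha power adding ~0.20 R² beyond the bedside
score alone — the planted prognostic structure, recovered from the EEG.
The montage screen (step 03) finds the power and median-connectivity
features almost perfectly reliable across montages (r ≥ 0.99) while the
graph features are not — the expected behaviour of high-variance network
summaries at low channel counts.

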