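# dticonn

Structural-connectivity analysis for two-group diffusion MRI cohorts, built
around the question of separating Parkinson's disease (PD) patients from
SWEDD patients (scans without evidence of dopaminergic deficit — clinically
PD-like subjects with a normal dopamine-transporter SPECT). The two groups
call for different therapies, so a non-SPECT, MRI-based discriminator is of
real clinical interest. `dticonn` implements the full analysis chain as a
tested Python library plus CLI, together with synthetic diffusion phantoms
and synthetic cohorts so that every stage can be validated end to end
without access-controlled imaging data.

## The method

1. **Tensor model.** Per voxel, the diffusion-weighted signal follows the
   Stejskal-Tanner monoexponential model
   `S = S0 · exp(−b gᵀ D g)`, with `D` a 3×3 symmetric tensor (mm²/s).
   `D` is estimated by log-linear least squares over its six unique
   components; eigen-decomposition gives `λ1 ≥ λ2 ≥ λ3` and the principal
   eigenvector `e1`. The default acquisition is a single shell at
   b = 1000 s/mm² with 64 gradient directions plus one b0.
2. **FACT tractography.** Deterministic streamlines are launched from the
   center of every masked voxel, stepping to the exact exit point of each
   voxel along `e1` (sign-aligned with the incoming direction) and
   terminating on mask exit, an invalid voxel, or a direction change
   greater than 60°. The tracking mask is the tissue mask dilated by one
   voxel (26-connectivity).
3. **Connectome.** An undirected, weighted network over 39 motor-related
   regions (19 bilateral pairs + brainstem: motor/premotor cortex, DLPFC,
   cingulate motor area, SMA, parietal lobe, subcortical nuclei). Edge
   weight = number of streamlines with one endpoint in each region; entries
   below 5 fibers are zeroed as unstable.
4. **Group statistics.** Per edge, the observed statistic is the difference
   of group means of fiber counts. Significance comes from 10,000 random
   reassignments of subjects to the two groups (sizes fixed), with
   family-wise error controlled by the single-step max-|T| permutation
   distribution.
5. **Clinical correlation.** Surviving edges are screened by Spearman rank
   correlation between pooled fiber counts and an MDS-UPDRS-like integer
   motor score, Holm-Bonferroni corrected.
6. **Classification.** Edges significant in both screens feed a linear SVM
   evaluated by leave-one-out cross-validation (one fold per subject,
   features standardized per training fold), reported as sensitivity,
   specificity, and accuracy.

## Worked example

The demo configuration generates a synthetic cohort of 37 + 40 subjects
over the 39 motor regions with four planted connections — increased
2.5-fold in the PD-like group and linearly driving the motor score — and
runs the statistics chain:

```yaml
# demo.yaml
out_dir: demo_out
seed: 11
n_permutations: 10000
cohort:
  effect_edges: [[2, 32, 2.5], [15, 17, 2.5], [15, 19, 2.5], [16, 18, 2.5]]
  score_edges:  [[2, 32, 0.15], [15, 17, 0.15], [15, 19, 0.15], [16, 18, 0.15]]
  seed: 11
```

```bash
dticonn run --config demo.yaml
```

`demo_out/group_test.csv` then contains exactly the four planted edges as
significant (max-statistic corrected p < 0.05):

```
                                  edge  observed_stat  p_corrected
                L_precentral|L_putamen     -30.510135       0.0001
    R_posteriorcingulate|R_paracentral     -40.585811       0.0001
R_posteriorcingulate|R_superiorfrontal     -31.869595       0.0001
       L_paracentral|L_superiorfrontal     -22.958784       0.0016
```

(the statistic is mean(SWEDD) − mean(PD), so planted increases in the
PD-like group appear negative). All four survive the Holm-corrected
Spearman screen against the synthetic motor score with rho ≈ 0.62–0.73,
and `demo_out/classification.json` reports the LOOCV linear SVM on those
four features:

```
sensitivity 91.89   specificity 92.50   accuracy 92.21   (77 folds)
```

Phantom-side, a noiseless straight bundle of 50 voxels between two labeled
regions yields a connectivity weight of exactly 50, and the same bundle
with a sharp 90° elbow yields 0 — the direction change exceeds the 60°
angle threshold, so no streamline connects the regions.

## Layout

```
src/dticonn/
  acquisition.py   # AcquisitionScheme, DWIVolume, default 64+1 scheme
  tensor.py        # log-linear tensor fit, eigen-structure, FA
  tracking.py      # FACT propagation, TrackingParams, Streamline
  connectome.py    # Parcellation, fiber-count matrices, region table
  stats.py         # permutation test, Spearman, Holm-Bonferroni
  classify.py      # LOOCV linear SVM, confusion metrics
  synthetic.py     # bundle phantoms and overdispersed-count cohorts
  pipeline.py      # YAML-configured end-to-end orchestration
  cli.py           # dticonn simulate-phantom / track / group-test / ... / run
  data/motor_regions.tsv
docs/methods.md    # model assumptions, parameter choices, limitations
```
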