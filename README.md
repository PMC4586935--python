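# graspref

Two-sided evidence combination for reference-frame decoding of multivoxel
activity patterns. The package decides whether patterns encode movement
targets in **gaze-centered (GC)** or **body-centered (BC)** coordinates by
combining two complementary measures over pairs of trial configurations:

- **classification (a)** — leave-one-run-out accuracy of a binary linear
  SVM on a pair; evidence that two representations are *distinct*;
- **cross-classification (o)** — accuracy of a trained classifier when one
  trained configuration is replaced by a non-trained one, routed to the
  *receiving pair* {replaced, replacement}; evidence that they are *common*.

Each frame's aggregate mixes exactly two a's and two o's, so score-type
imbalance and pure gaze-direction coding cancel in the GC−BC contrast; a
conjunction rule requires significant evidence on both sides. The pipeline
runs from per-run GLM t-patterns through searchlight mapping, group GLM,
cluster thresholding, and ROI statistics, and is validated end to end on
synthetic data with known ground-truth coding.

## Modules

| module | contents |
| --- | --- |
| `graspref.design_space` | the four trial configurations, six condition pairs, per-hypothesis common/distinct predictions |
| `graspref.synthetic` | pattern/schedule/BOLD/volume simulators with controllable coding schemes (GC, BC, gaze-direction, mixed, null) and modality models (shared, independent, switching) |
| `graspref.glm` | 28-regressor per-run design, canonical HRF, DCT high-pass, OLS + t contrasts, BOLD→t-pattern assembly |
| `graspref.decoding` | z-scoring, LORO pair classifiers, replacement-routed cross-classification, cross-modal transfer |
| `graspref.evidence` | frame aggregates/contrast, conjunction, gaze-direction control test, significance flags |
| `graspref.searchlight` | sphere indexing (7 mm radius, mm distances via the affine), per-sphere scoring, sphere-to-voxel averaging |
| `graspref.group_roi` | group GLM (subject intercepts + condition cells), cluster extent thresholding, nearest-peak ROI placement, ROI tests |
| `graspref.io` / `graspref.pipeline` / `graspref.cli` | NIfTI/TSV/YAML formats with JSON sidecars, the end-to-end pipeline, the `graspref` CLI |

## CLI

```sh
graspref report --out pairs.tsv                 # condition-pair predictions
graspref simulate --scheme gaze_centered --snr 5 --seed 1 --out sim
graspref decode --patterns sim_vis.tsv --out evidence.tsv
graspref searchlight --patterns-vis stack.nii --mask mask.nii --radius-mm 7 --out-dir maps/
graspref group --maps maps/ --alpha 0.05 --min-cluster 250 --out-dir group/
graspref roi --tmap group/tmap_all_conditions.nii --ref "-35,-47,50" --out roi.json
graspref run-all --out-dir out --seed 0         # demo pipeline end to end
```

Exit codes: 0 success, 2 validation/config error, 3 stage failure.

## Notes on inference

Single-dataset significance flags use a variance-corrected resampled
t-test over folds (leave-one-run-out folds overlap in training data, so
the naive t-test is anti-conservative). Group-level flags are plain
t-tests across independent datasets/subjects. Aggregate scores use
pair-mode cross-classification scoring; conjunction flags use
replacement-only scoring (see module docstrings for why the two measures
need different routing).
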