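# supradecode

Supramodal multivoxel pattern decoding: does the brain encode *actions*
in a way that survives the change of sensory modality — and of visual
experience altogether?

`supradecode` is a tested, reusable implementation of the MVPA workflow
used to ask that question of fMRI beta patterns from sighted and
congenitally blind participants who heard (and, if sighted, watched)
hand actions vs. environmental non-action stimuli, and performed motor
pantomimes. It provides:

* a **synthetic beta-pattern generator** emulating the full design (14
  sighted + 8 blind subjects; 20/10 sounds, 23/11 videos, pantomime
  probes) with ground-truth informative voxel clusters — a shared
  "supramodal" set plus modality-specific sets — so every stage is
  testable without any data download;
* **assembly**: stimulus-level up/down-sampling to balanced classes,
  per-voxel standardise-then-tanh scaling into (−1, 1), stratified
  4-fold assignment that never splits a stimulus (or its up-sampled
  duplicate) across train and test;
* **soft-margin linear SVM** decoding, C fixed data-driven as
  1/mean‖x‖², with the weight vector w = Σαᵢyᵢxᵢ exposed for feature
  selection;
* **recursive feature elimination** (drop the 2% of voxels with
  smallest |w| per iteration, 3D cluster correction of the survivors)
  **inside nested cross-validation**, with best-iteration and
  best-fold selection;
* the **combined supramodal classifier** and **knock-out mask**
  analyses: exclusion, restriction, cross-condition / cross-group
  generalization, pantomime probing;
* **nonparametric inference**: training-label permutation tests,
  exact Wilcoxon signed-rank, Fisher combination, exact binomial;
* NIfTI + TSV dataset interchange, JSON/TSV reports, and a
  `supradecode` CLI (`simulate | fit | knockout | report`).

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

```python
from supradecode.config import shared_signal_config
from supradecode.pipeline import run_experiment

# shared-signal regime: the supramodal voxel set carries most signal
result = run_experiment(shared_signal_config(seed=1), with_permutations=True)

print("best fold:", result.best_fold)
for name, cell in result.within.items():
    print(f"within {name}: {cell['accuracy']:.3f} (p={cell['p_perm']:.3g}, "
          f"{cell['n_voxels']} voxels)")
print("supramodal:", f"{result.supramodal.pooled_accuracy:.3f}",
      f"over {result.supramodal.knockout.size} voxels (p={result.supramodal_p:.3g})")
print("exclusion Fisher p:", f"{result.fisher_exclusion_p:.2e}")
print(result.restricted_table.cells[["train_condition", "test_condition",
                                     "accuracy", "p_perm"]].to_string(index=False))
```

prints (seed 1):

```
best fold: 3
within sighted_visual: 0.935 (p=0.01, 31 voxels)
within sighted_auditory: 0.944 (p=0.01, 389 voxels)
within blind_auditory: 0.972 (p=0.01, 139 voxels)
supramodal: 0.957 over 143 voxels (p=0.01)
exclusion Fisher p: 1.18e-07
 train_condition   test_condition  accuracy  p_perm
  sighted_visual   sighted_visual  0.941558    0.01
  sighted_visual sighted_auditory  0.960317    0.01
  sighted_visual   blind_auditory  0.902778    0.01
sighted_auditory   sighted_visual  0.961039    0.01
sighted_auditory sighted_auditory  0.920635    0.01
sighted_auditory   blind_auditory  0.944444    0.01
  blind_auditory   sighted_visual  0.948052    0.01
  blind_auditory sighted_auditory  0.912698    0.01
  blind_auditory   blind_auditory  0.930556    0.01
```

Reading: each condition decodes action vs. non-action far above the
50% chance level within itself; removing the 143 knock-out voxels
selected by the pooled supramodal classifier significantly lowers
within-condition accuracy (Wilcoxon per condition, Fisher-combined
p ≈ 1e−7); and classifiers *restricted* to those voxels generalise
across modality and group — every off-diagonal train-on-one /
test-on-another cell stays permutation-significant. That combination
is the signature of a supramodal action representation. In the
`modality_dominant` preset (no shared signal) the same pipeline shows
the opposite pattern: within-condition decoding works but cross-modal
cells drop to chance.

The same analysis from the shell:

```sh
supradecode simulate --preset shared_signal --seed 1 --out scratch/ds
supradecode fit      --preset shared_signal --seed 1 --dataset scratch/ds --out scratch/fit
supradecode knockout --preset shared_signal --seed 1 --out scratch/ko
```

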