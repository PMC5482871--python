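# hiercls

Hierarchy-constrained deep metric learning for multi-class histopathology
image classification.

The training objective combines a softmax classification loss `J` with a
quadruplet distance-constraint hinge loss `E_t` that pushes l2-normalized
embeddings into a tiered ordering driven by a two-level label taxonomy
(superclass / subclass, e.g. benign/malignant over eight tumor types):

```
D(x, p+) + m1  <  D(x, p-) + m2  <  D(x, n)          (m1 < m2)
E = lam * J + (1 - lam) * E_t                         (lam = 0.5 by default)
```

where `p+` shares the anchor's subclass, `p-` shares only its superclass and
`n` comes from the other superclass.  The package ships:

- `hiercls.hierarchy` — two-level taxonomies and pairwise label relations
- `hiercls.losses` — softmax, quadruplet hinge and combined losses with
  analytic gradients (checked against finite differences)
- `hiercls.sampling` — quadruplet mining and hierarchy-balanced batching
- `hiercls.metrics` — patient-level / image-level recognition rates,
  confusion matrices, cross-validation summaries (mean ± sd)
- `hiercls.data_io` — image-manifest CSVs, patient-wise stratified splits,
  5-fold CV assignment, augmentation leakage audit
- `hiercls.augmentation` — intensity/rotation/flip/translation operators and
  class-balancing oversampling (training split only)
- `hiercls.synthetic` — a deterministic generator of hierarchy-structured
  synthetic images (patients, magnifications, configurable imbalance), so the
  whole pipeline runs with no external dataset
- `hiercls.model` — a small convolutional backbone implemented directly on
  NumPy (im2col convolutions, hand-written backprop, SGD + momentum) with an
  l2-normalized embedding head and a softmax classifier head

No GPU or deep-learning framework is required.

## Test

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (loss-oracle
equivalence, gradient correctness, metric identities, miner soundness,
oversampling exactness, desk-scale structure recovery, determinism); the
structure-recovery tests train two models and take about a minute.

## CLI

The pipeline is stage-wise; every stage reads one YAML config and the
artifacts of the previous stage:

```
hiercls generate --config run.yaml          # synthetic dataset + manifest
hiercls split    --config run.yaml          # patient-wise train/val/test
hiercls augment  --config run.yaml          # balance classes by oversampling
hiercls train    --config run.yaml          # SGD on the combined loss
hiercls eval     --config run.yaml --split test
hiercls summarize run1/metrics_test.json run2/metrics_test.json   # mean ± sd
```

Minimal `run.yaml`:

```yaml
seed: 0
out_dir: runs/demo
synthetic: {patients_per_subclass: 4, images_per_patient: 8, image_size: 64}
split: {fractions: [0.5, 0.25, 0.25]}
backbone: {input_size: 64, embedding_dim: 64}
training: {iterations: 240, batch_size: 32, m1: 0.2, m2: 0.4, lam: 0.5}
```

## Notes

- Splits are always by patient: no subject contributes images to more than
  one of train/validation/test, and `audit_no_leakage` fails loudly if an
  augmented image derives from a held-out patient.
- Determinism: all randomness flows from explicit seeds; repeated runs
  produce byte-identical datasets, augmented images and training logs on the
  same machine.
- Default margins `m1=0.2, m2=0.4` and embedding dimension 64 are package
  choices (config-exposed); distances are plain Euclidean on unit-norm
  embeddings, with a squared variant behind a flag.
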