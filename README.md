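# patchreg

Patch-based dual-hierarchical CNN registration of 3D volumetric brain
images.  A coarse (level-1) network learns large deformations and a fine
(level-2) network learns the residual small deformations left after the
coarse stage; dense displacement fields are assembled by sliding-window
inference with overlap averaging.  Training samples are rebalanced by a
self-feedback pass that maps prediction errors, histograms them into
integer bins, and allocates extra patches inversely to bin frequency
(exponent `alpha`; smaller values flatten the allocation).

The package is self-contained: a synthetic module generates textured
brain-like phantoms, region labels, and smooth invertible ground-truth
displacement fields, so the whole pipeline runs end-to-end with no
external data.  The network stack (3D convolution, PReLU, max pooling,
dropout, dense output heads, Adam) is implemented in NumPy with
hand-written backward passes — no deep-learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `patchreg.volumes_io` | NIfTI / TIFF-stack I/O, histogram matching, isotropic downsampling |
| `patchreg.deform` | warping, field scaling/composition, mean filtering, Jacobian determinants, distance maps |
| `patchreg.sampling` | fixed-grid patch extraction and self-feedback sample allocation |
| `patchreg.nn` / `patchreg.network` | NumPy layer library and the dual-branch patch regression model |
| `patchreg.training` | pretraining, self-feedback fine-tuning, level-2 residual training |
| `patchreg.predict` | overlap-averaged sliding-window field assembly, two-level registration |
| `patchreg.evaluate` | Dice, endpoint-error statistics, correlation points, Jacobian fold reports |
| `patchreg.synthetic` | phantom / field / corpus generation |
| `patchreg.cli` | `patchreg` command-line entry point |

Conventions: arrays are `(z, y, x)` indexed; displacement fields are
`(Z, Y, X, 3)` with components `(ux, uy, uz)` in voxel units, pull
semantics (a warped voxel `v` samples the moving image at `v + u(v)`);
fields are stored as 4D NIfTI.

## CLI

```bash
patchreg simulate     --out corpus/ --seed 7 --preset desk
patchreg train-level1 --data corpus/ --out-dir run/l1 --preset desk
patchreg feedback     --data corpus/ --model run/l1/level1_pretrained.npz --out-dir run/fb
patchreg train-level2 --data corpus/ --model-l1 run/fb/level1_final.npz --out-dir run/l2
patchreg predict      --model-l1 run/fb/level1_final.npz --model-l2 run/l2/level2_final.npz \
                      --fixed corpus/val_013/fixed.nii.gz --moving corpus/val_013/moving.nii.gz \
                      --out-dir run/pred
patchreg evaluate     --pred-field run/pred/field_level1.nii.gz \
                      --true-field corpus/val_013/gt_field.nii.gz \
                      --labels-a corpus/val_013/labels_fixed.nii.gz \
                      --labels-b corpus/val_013/labels_moving.nii.gz --out run/report.json
```

Two presets are built in: `desk` (48^3 phantoms, window 16, output 9 —
fits a single CPU) and `paper` (window 64, step 32, output 9, 200-epoch
budgets — the full-scale profile, impractical without a GPU).  Options
layer as defaults < preset < `--config file.yaml` < flags; each run
writes its resolved configuration next to its outputs.

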