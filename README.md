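# ailabel3d

AI-assisted label generation for 3D multi-modal MRI tumor segmentation.

Expert voxel-level tumor annotation is the bottleneck of supervised medical
image segmentation. `ailabel3d` implements a two-step framework that turns a
pair of *coarse* expert outlines into a full-quality training label:

1. **Unsupervised feature clustering** (`ailabel3d.featcluster`) — a
   dual-branch 3D CNN embeds each voxel of a T1/T2 volume pair into 60
   features and assigns it the argmax channel as a cluster label. Training
   minimises a self-labelling cross-entropy plus a 3-axis L1 spatial
   continuity penalty; unused clusters die off ("adaptive merging"), so the
   initial 60 clusters collapse to a handful of tissue-aligned ones without
   any supervision.
2. **Seeded cluster-aware refinement** (`ailabel3d.refine`) — the two expert
   outlines are added, the cluster map is restricted to that region, seeds
   are placed stratified over the clusters present, each seed grows to its
   full 6-connected cluster component, components larger than 3× the
   estimated tumor volume are discarded, and the survivors are united into
   the AI-assisted label (AI-L).

The package also provides a dual-channel 3D U-Net (`ailabel3d.unet3d`) to
measure how well AI-L trains a downstream segmenter compared with expert
labels, evaluation metrics and a blinded-comparison harness
(`ailabel3d.evalx`), NIfTI I/O and preprocessing (`ailabel3d.io_prep`), and
a synthetic phantom generator (`ailabel3d.phantom`) that emulates the
statistical structure of a clinical cohort so everything is runnable and
testable offline on one CPU core.

All networks run on the package's own NumPy reverse-mode layer library
(`ailabel3d.nn`) — no deep-learning framework required.

See [docs/methods.md](docs/methods.md) for the full description of models,
losses, and design choices.

## Worked example

```python
import numpy as np
from ailabel3d import phantom, featcluster, refine, evalx
from ailabel3d.io_prep import VolumePair, znormalize

# A synthetic case: T1/T2 volumes, ground-truth tumor, two coarse outlines.
case = phantom.make_phantom(shape=(48, 48, 16), rng_seed=200)
pair = VolumePair(t1=znormalize(case.pair.t1), t2=znormalize(case.pair.t2),
                  case_id="demo", patient_id="demo")

# Step 1: unsupervised clustering (60 clusters collapse as training runs).
cfg = featcluster.ClusterTrainConfig(lr=0.1, momentum=0.9, batch_size=1,
                                     max_epochs=30, patience=30, rng_seed=0)
model, history = featcluster.train_unsupervised([pair], cfg)
clusters = featcluster.assign_clusters(featcluster.forward_embed(pair, model))
print(history[0].n_active_clusters, "->", history[-1].n_active_clusters)

# Step 2: coarse expert outlines + clusters -> AI-assisted label.
ail, provenance = refine.generate_ai_label(clusters, case.el_t1, case.el_t2,
                                           n_seeds=10, rng_seed=0)
print("AI-L vs ground truth Dice:", round(evalx.dice(ail, case.tumor_mask), 3))
```

Output (deterministic for these seeds; ~3 minutes on one CPU core):

```
60 -> 43
AI-L vs ground truth Dice: 0.574
```

A single 48×48×16 case and 30 epochs is a deliberately small demo: cluster
collapse stalls well short of full convergence at this scale, so oversized
non-tumor components leak into the AI-L and cap its Dice. See
[docs/methods.md](docs/methods.md) §7 for the problem-size discussion.

## Command line

The `ailabel3d` CLI exposes the pipeline stage by stage:

```sh
ailabel3d phantom make --n 5 --shape 48,48,16 --seed 7 --out cohort/
ailabel3d prep --t1 t1.nii.gz --t2 t2.nii.gz --out prepped/ --shape 48,48,16
ailabel3d cluster train --data cohort/ --config cluster.yaml --out model/
ailabel3d refine --clusters model/case_000_clusters.nii.gz \
    --el-t1 cohort/case_000_el_t1.nii.gz --el-t2 cohort/case_000_el_t2.nii.gz \
    --seeds 10 --rng 0 --out case_000_ail.nii.gz
ailabel3d unet train --data cohort/ --labels ail/ --out unet/
ailabel3d eval metrics --pred pred.nii.gz --ref truth.nii.gz
ailabel3d eval blind-make --cases case_000,case_001 --seed 1 --out trials.csv
ailabel3d eval blind-tally --sheet trials.csv --key trials_unblinding_key.csv
```

## Layout

```
src/ailabel3d/
  nn.py           NumPy reverse-mode layers, optimisers
  io_prep.py      NIfTI I/O, resampling, z-normalisation, cohort splitting
  phantom.py      synthetic multi-tissue MRI phantom generator
  featcluster.py  step 1 — unsupervised differentiable feature clustering
  refine.py       steps 2–3 — seeded cluster-aware label refinement
  unet3d.py       downstream dual-channel 3D U-Net
  evalx.py        metrics, homogeneity analysis, blinded comparison
  cli.py          click command-line interface
```
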