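"""Train a miniature two-step cascade on tiny phantoms and watch the loss.

The compound loss is soft Dice + binary cross entropy; for the cascade the
step-2 (patch) term only contributes once step 1 finds voxels above the 0.8
seeding threshold, so the printed patch counts start at zero and grow as the
coarse model becomes confident.  Runs in under a minute.
"""

from chpseg import CascadeConfig, NetworkSpec, PhantomParams, TrainConfig
from chpseg import generate_cohort, preprocess, PreprocessConfig, train

pcfg = PreprocessConfig(target_shape=(48, 48, 48))
pairs = []
for v, m in generate_cohort(4, PhantomParams(shape=(48, 48, 48),
                                             target_volume_fraction=0.004), 7):
    pairs.append((preprocess(v, pcfg)[0], preprocess(m, pcfg)[0]))

nets, log = train(
    pairs[:3],
    TrainConfig(mode="2step", epochs=8, seed=0, batch_lowres=1,
                max_patches_per_image=4, batch_patches=8),
    CascadeConfig(lowres_shape=(12, 12, 12), patch_size=8),
    val_pairs=pairs[3:],
    net_spec=NetworkSpec(levels=2, base_filters=4, norm_groups=4),
)
for row in log:
    print(f"epoch {row['epoch']}: train loss {row['train']['total']:.3f} "
          f"({row['train']['n_patches']} patches), "
          f"val loss {row['val']['total']:.3f}, lr {row['lr']:.1e}")
print("\nA nonzero patch count means step 1 is confident enough to engage "
      "step 2; the total falls as both stages learn.")
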