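"""Multi-label context classification when several sensors disappear.

A classification head is stacked on the trained encoder and the whole
stack is fine-tuned under structured input noise with an
instance-weighted loss (inverse class frequency; zero weight at
unreported labels).  At test time three phone modalities are dropped to
the sentinel; the baseline is a same-capacity classifier trained on
data where missing entries are simply filled with -1.
"""

import numpy as np

from mmaae import GeneratorConfig, generate_dataset, make_user_folds
from mmaae.aae import TrainConfig
from mmaae.experiments import (
    PipelineConfig, evaluate_fold_scenario, fit_fold,
)

dataset, _ = generate_dataset(
    GeneratorConfig(n_users=20, instances_per_user=(150, 250), seed=42)
)
plan = make_user_folds(dataset.user_ids, k=5, rng=np.random.default_rng(0))

cfg = PipelineConfig()
cfg.recon_cfg = TrainConfig.reconstruction_defaults(seed=1)
cfg.clf_cfg = TrainConfig.reconstruction_defaults(seed=2)
art = fit_fold(dataset, plan[0][0], plan[0][1], cfg, methods=("aae", "fill"))

for drop in ((), ("Acc", "Gyro", "Aud")):
    label = "none" if not drop else "+".join(drop)
    ba_aae = evaluate_fold_scenario(art, drop, "aae").macro["balanced_accuracy"]
    ba_fill = evaluate_fold_scenario(art, drop, "fill").macro["balanced_accuracy"]
    print(f"dropped: {label:13s} macro BA  AAE {ba_aae:.3f}   fill(-1) {ba_fill:.3f}")
print("(balanced accuracy = (sensitivity+specificity)/2, macro-averaged "
      "over labels; the noise-trained AAE classifier degrades gracefully "
      "while the fill baseline collapses on unseen sentinel patterns)")
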