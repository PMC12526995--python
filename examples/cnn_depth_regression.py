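"""Train the spectrogram CNN on single-cycle crops, subject-exclusive.

Each detected compression cycle becomes a 64x64 grayscale spectrogram crop
labelled with its true depth.  One subject is held out entirely; the CNN
(283,329 parameters) is trained with SGD + momentum and early stopping on
the rest and scored on the held-out subject.  Takes a few minutes on one
CPU at this reduced size.
"""

import numpy as np

from mdcpr import RadarConfig, campaign_cycles
from mdcpr.cnn import TrainConfig, build_cnn, evaluate_cnn, train_cnn
from mdcpr.synthetic import generate_campaign

config = RadarConfig()
manifest = generate_campaign(
    config,
    subjects=3,
    cases={1: 0.0},
    depths_cm=(3.0, 4.5, 6.0),
    rates_cpm=(100.0,),
    seed=11,
    duration_s=8.0,
    noise_snr_db=20.0,
)
cycles = campaign_cycles(manifest, config, with_images=True, image_tfr="stft")
train = cycles[cycles["subject"] != 2]
test = cycles[cycles["subject"] == 2]
print(f"{len(train)} training crops, {len(test)} held-out crops (subject 2)")

model = build_cnn(seed=1)
print(f"trainable parameters: {model.n_params}")
history = train_cnn(
    model,
    np.stack(train["image"].to_list()),
    train["depth_ref_cm"].to_numpy(),
    TrainConfig(max_epochs=20, patience=6, seed=1),
)
print(f"stopped after {len(history)} epochs; "
      f"best validation epoch {history.attrs['best_epoch']} "
      f"(val RMSE {np.sqrt(history.attrs['best_val_loss']):.2f} cm)")

err = evaluate_cnn(model, np.stack(test["image"].to_list()),
                   test["depth_ref_cm"].to_numpy())
print(f"held-out subject RMSE: {err:.2f} cm")
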