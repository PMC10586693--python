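"""Train the marker augmenter on a synthetic corpus and evaluate it.

The augmenter maps 20 noisy keypoints (+ height, mass) to the 43-marker
anatomical set used by inverse kinematics.
"""
import numpy as np

from markerless import generate_augmenter_corpus, train_augmenter, augment

corpus = generate_augmenter_corpus(n_subjects=15, duration=2.0, seed=0)
aug = train_augmenter(corpus, seed=1)
print("held-out marker RMSE (mm):",
      {k: round(v * 1e3, 1) for k, v in aug.heldout_rmse.items()})

trial = [t for t in corpus if t.split == "test"][0]
rng = np.random.default_rng(5)
noisy = trial.keypoints3d + rng.normal(0, 0.018, trial.keypoints3d.shape)
pred = augment(noisy, trial.height, trial.mass, aug, times=trial.times)
hat = np.stack([pred.positions[n] for n in trial.marker_names], axis=1)
print("marker RMSE with 18-mm keypoint noise: %.1f mm"
      % (np.sqrt(np.mean((hat - trial.markers) ** 2)) * 1e3))
# the windowed regressor suppresses most of the injected noise
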