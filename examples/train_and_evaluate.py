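"""Noise-train a small CNN and compare its SSNR threshold with a clean twin.

Trains two networks on the same synthetic shape categories -- one on clean
images only, one on an equal mix of clean images and images in pixelated
Gaussian noise (SSNR 0.2-0.99) -- then fits a 4-parameter logistic to each
accuracy-by-SSNR curve and reports the 50% SSNR threshold.
"""

import numpy as np

from noisyvision import network, psychometrics as psy, synthetic, training

ds = synthetic.generate_image_dataset(4, 40, 10, canvas=64, seed=0)
tr_im, tr_lab, _ = ds.subset("train")
te_im, te_lab, _ = ds.subset("test")

noise_mix = training.NoiseMixSpec(
    [
        training.MixComponent("clean", None, 0.5),
        training.MixComponent("gaussian", (0.2, 0.99), 0.5),
    ]
)

levels = np.arange(0.05, 1.0001, 0.05)
for name, mix in [("clean-trained", training.CLEAN_MIX), ("noise-trained", noise_mix)]:
    model = network.SmallCNN(canvas=64, n_classes=4, seed=0)
    model, log = training.train_model(model, tr_im, tr_lab, mix=mix, cfg=training.TrainConfig(epochs=25, seed=0))
    curve = training.accuracy_by_ssnr(model, te_im, te_lab, "gaussian", levels, n_noise=3, seed=1)
    fit = psy.fit_logistic4(curve, guess_rate=0.25)
    est = psy.threshold_at(fit, 0.5)
    print(f"{name}: clean accuracy {curve.values[-1]:.2f}, "
          f"50% SSNR threshold {est.threshold:.3f} (valid={est.valid})")

print()
print("A lower threshold means the network recognises objects at higher")
print("noise levels; noise training shifts the psychometric curve leftward")
print("without sacrificing clean accuracy.")
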