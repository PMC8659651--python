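"""Decode object category from synthetic voxel patterns and run RSA.

Generates run-structured voxel responses as a noisy linear readout of one
network layer, decodes the category with leave-one-run-out SVM
cross-validation, and uses representational similarity analysis to identify
which layer generated the patterns.
"""

import numpy as np

from noisyvision import network, neural, synthetic, training

ds = synthetic.generate_image_dataset(4, 30, 4, canvas=32, seed=0)
tr_im, tr_lab, _ = ds.subset("train")
te_im, te_lab, _ = ds.subset("test")

model = network.SmallCNN(canvas=32, n_classes=4, channels=(8, 16), fc_units=32, seed=0)
model, _ = training.train_model(model, tr_im, tr_lab, cfg=training.TrainConfig(epochs=10, seed=0))

acts = [model.forward_activations(im) for im in te_im]
feats = {name: np.stack([a[name] for a in acts]) for name in acts[0]}

gen_layer = "conv2"
for snr in (0.0, 1.0, 8.0):
    vp = synthetic.simulate_voxel_patterns(
        feats[gen_layer], n_voxels=100, n_runs=6, snr=snr, seed=0,
        categories=te_lab, ground_truth_layer=gen_layer,
    )
    acc = neural.decode_category(vp.data, "clean", "clean")
    print(f"snr {snr:4.1f}: leave-one-run-out decoding accuracy {acc:.3f} (chance 0.25)")

vp = synthetic.simulate_voxel_patterns(
    feats[gen_layer], 100, 6, snr=8.0, seed=0, categories=te_lab, ground_truth_layer=gen_layer
)
d = vp.data
mean_pat = np.stack([d.responses[d.stimulus == s].mean(axis=0) for s in range(len(te_im))])
neural_rdm = neural.build_rdm(mean_pat)
print()
print("RSA correlation between the synthetic 'neural' RDM and each layer's RDM:")
for name in feats:
    r, z = neural.rsa_compare(neural_rdm, neural.build_rdm(feats[name]))
    marker = "  <-- generating layer" if name == gen_layer else ""
    print(f"{name:8s} r = {r:.3f}{marker}")
print()
print("Decoding rises from chance to perfect as the signal-to-noise ratio of")
print("the voxel readout grows, and RSA peaks at the layer that generated")
print("the patterns -- the logic used to match cortical areas to layers.")
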