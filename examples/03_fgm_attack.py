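"""Probe model robustness with the fast-gradient method (FGM).

Trains one model on a synthetic train/validation split, then rescores each
held-out window after adding delta = epsilon * sign(dJ/dx) to the embedding
output (path 1) and the PseKNC features (path 2). The two metric rows show
how much a worst-case sign perturbation of the inputs moves performance;
a small gap indicates robustness to input noise such as sequencing errors.
"""

from ac4cnet import (
    FgmConfig,
    NetworkConfig,
    SyntheticSpec,
    TrainConfig,
    attack_evaluate,
    generate_synthetic,
    train_fold,
)

records = generate_synthetic(
    SyntheticSpec(n_pos=100, n_neg=100, length=51, motif_rate=0.5, seed=4)
)
train, val = records[:80] + records[100:180], records[80:100] + records[180:]
net = NetworkConfig(d_model=32, gru_hidden=32, heads=4,
                    conv_channels=(8, 16, 32), classifier_hidden=32, k=2)
model, _ = train_fold(train, val, net,
                      TrainConfig(epochs=4, batch_size=32, seed=0), seed=0)

clean, attacked = attack_evaluate(model, val,
                                  FgmConfig(epsilon=0.1, target="both"))
print(f"{'':>9}" + "".join(f"{k:>8}" for k in clean.as_dict()))
print(f"{'clean':>9}" + "".join(f"{v:>8.3f}" for v in clean.as_dict().values()))
print(f"{'attacked':>9}" + "".join(f"{v:>8.3f}" for v in attacked.as_dict().values()))
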