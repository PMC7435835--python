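"""Walk the 1D CNN architecture arithmetic without training anything.

Prints the layer-by-layer output shapes of the reference 10-layer model
(6000-sample input halving to a 5x45 feature map, flattened to 225
features) and the closed-form parameter count, then instantiates the
network to confirm the framework agrees with the arithmetic.
"""

from apneakit import ModelConfig, build_model, count_parameters, shape_table

cfg = ModelConfig()  # reference architecture: 10 feature + 4 class layers

print(f"{'layer':<18} {'output shape'}")
for row in shape_table(cfg):
    if row.channels > 1:
        print(f"{row.layer_name:<18} ({row.length}, {row.channels})")
    else:
        print(f"{row.layer_name:<18} ({row.length},)")

total = count_parameters(cfg)
trainable = count_parameters(cfg, trainable_only=True)
print()
print(f"parameters (incl. batch-norm moving stats): {total:,}")
print(f"trainable parameters:                       {trainable:,}")
print(f"in millions, 1 decimal:                     {total / 1e6:.1f}")

model = build_model(cfg, seed=0)
assert model.n_parameters() == total
print("instantiated network agrees with the closed form.")
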