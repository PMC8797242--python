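"""Train tiny reference models across beta and print the rate/distortion
table: as beta grows, the KL rate falls (sparser code) and the distortion
(reconstruction error) rises."""
import dataclasses

import statcell as sc

params = sc.PhantomParams(
    image_shape=(32, 32), cell_semiaxes=(12.0, 9.0), nucleus_semiaxes=(5.5, 4.0)
)
ds = sc.generate_population(100, {"control_blank": 1.0}, params, seed=11)
data = sc.TrainData.from_phantoms(ds, "reference")
spec = sc.NetworkSpec(
    dimensionality=2, input_shape=(32, 32), input_channels=2,
    channels=(4, 8, 16, 32), latent_dim=16, seed=5,
)
cfg = sc.TrainConfig(batch_size=8, epochs=15, seed=2, learning_rate=2e-3)
table = sc.beta_sweep(
    data, [0.0, 0.5, 1.0], cfg,
    model_factory=lambda i: sc.VAEModel(dataclasses.replace(spec, seed=5 + i)),
)
print(table.round(3).to_string(index=False))
# rate = mean test KL (nats); distortion = mean test sum-of-squares error;
# active_dims = latent dimensions whose mean KL exceeds 0.6 nats.
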