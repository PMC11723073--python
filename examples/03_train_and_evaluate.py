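"""Short adversarial training run and a Table-2-style metric report.

Trains the conditional WGAN-GP for a handful of generator steps (enough
to watch the losses move; the acceptance pipeline runs 500) and scores
the result with FID/MSE/SSIM against the real set.
"""

import numpy as np

from fundusgan import (GaussianStats, SynthConfig, TrainConfig, embed, evaluate,
                       fid, generate_sample, nn, prepare_conditions,
                       reports_to_csv, train, train_grader)

config = SynthConfig(side=64, n_samples=100, seed=3)
data = [generate_sample(config, i) for i in range(config.n_samples)]
grader, _ = train_grader(data, epochs=10, seed=3)

train_config = TrainConfig(steps=60, seed=3, log_every=20)
cache = prepare_conditions(data, grader, train_config.feature_layer)
result = train(data, grader, train_config, conditions_cache=cache)
print(f"completed {result.completed_steps} steps; "
      f"final Wasserstein gap {result.history[-1, 1]:.3f}, "
      f"interpolate gradient norm {result.history[-1, 6]:.3f}")


def gen_set(z_seed):
    rng = np.random.default_rng(z_seed)
    out = []
    for i in range(0, len(data), 25):
        cond = nn.Tensor(cache["conditions"][i:i + 25])
        z = nn.Tensor(rng.normal(size=(cond.shape[0], train_config.z_dim)))
        out.append(np.transpose(result.generator.forward(cond, z).data, (0, 2, 3, 1)))
    return np.concatenate(out)


report = evaluate(cache["images"], gen_set, repeats=3, seed=100,
                  method=train_config.resample.label, grader=grader)
print(f"{report.method}: FID {report.fid_mean:.3f}±{report.fid_sd:.3f}  "
      f"MSE {report.mse_mean:.5f}±{report.mse_sd:.5f}  "
      f"SSIM {report.ssim_mean:.3f}±{report.ssim_sd:.3f}")
reports_to_csv([report], "out/report.csv")
print("wrote out/report.csv")
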