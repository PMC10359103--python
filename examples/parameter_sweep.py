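"""Sweep the estimator's two free parameters on a reduced virtual dataset.

Generates a down-scaled version of the benchmark dataset (two geometry sets,
three unit sizes, five array offsets, fiber counts divided by 20), evaluates
the estimator over a (wavelet width, cluster radius) grid at 5 dB SNR, and
prints the error-score optimum for three accuracy/robustness weights.
"""

import numpy as np

from semgiz import evaluation as ev
from semgiz import virtual_experiment as vx

cfg = vx.default_config()
cfg.scale = 1 / 20
cfg.mu_ids = [450, 600, 750]
cfg.geometry_sets = vx.default_geometry_sets()[::3]
cfg.n_offsets = 5
cfg.seed = 3

dataset = vx.generate_dataset(cfg)
print(f"{len(dataset)} recordings")

result = ev.sweep(
    dataset,
    lambdas=np.geomspace(0.5e-3, 10e-3, 7),
    epsilons=np.geomspace(0.1, 10.0, 7),
    snr_list=(5.0,),
    alphas=(0.25, 0.5, 0.75),
    seed=0,
)
for alpha in (0.25, 0.5, 0.75):
    opt = result.optimal(5.0, alpha)
    print(
        f"alpha={alpha:4.2f}: best cell lambda={opt.lam * 1e3:5.2f} ms, "
        f"eps={opt.eps:5.2f} -> MAE={opt.mae * 1e3:.2f} mm, "
        f"untracked {int(opt.n_ne)}/{int(opt.n_total)}, ES={opt[f'es_{alpha:g}']:.3f}"
    )
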