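"""Generate a synthetic drug-response panel and fit the
uncertainty-weighted multi-task model.

The panel has 10 drugs sharing a rank-8 weight structure over 50 genes,
with true noise SDs spanning 0.1-2.0. After training, the learned
aleatoric scale sigma_t should rank-order the drugs by their true noise.
"""

import numpy as np
from scipy.stats import spearmanr

from pharmadapt import ModelConfig, MtlScenario, generate_mtl, train_mtl

scen = MtlScenario(
    n_genes=50, n_latent=8, n_tasks=10,
    samples_per_task=[400] * 10,
    noise_sd_per_task=list(np.linspace(0.1, 2.0, 10)),
    seed=0,
)
data, truth = generate_mtl(scen)
print(f"panel: {data.n_samples} samples x {data.n_genes} genes, "
      f"{data.n_tasks} drugs, {data.mask.sum()} observed responses")

cfg = ModelConfig(n_latent=32, dropout_rate=0.1, n_epochs=200,
                  learning_rate=0.02, batch_size=64, seed=100)
params, report = train_mtl(data, cfg)

print("\ndrug   true sigma   learned sigma")
for t in range(data.n_tasks):
    print(f"{t:4d}   {scen.noise_sd_per_task[t]:10.2f}   "
          f"{params.sigma()[t]:13.2f}")
rho = spearmanr(params.sigma(), scen.noise_sd_per_task).statistic
print(f"\nSpearman(learned, true) = {rho:.3f}")
print("A value near 1 means the model attenuates exactly the drugs whose "
      "assays are noisiest.")
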