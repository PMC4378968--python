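"""Train the genetic fuzzy standard additive model on selected genes.

Pipeline: AHP gene selection -> fuzzy c-means builds candidate rule bases
-> the genetic algorithm prunes the rule structure under an error +
rule-count fitness -> gradient descent with momentum fine-tunes every
rule parameter. Prints the fitness trajectory and the final rule base.
"""

import numpy as np

from ahpfsam import (
    GAConfig,
    SyntheticSpec,
    TrainConfig,
    evolve,
    generate,
    select_genes_ahp,
    train_supervised,
)
from ahpfsam.fsam import predict_batch

ds, truth = generate(SyntheticSpec(
    n_genes=200, n_samples=60, n_informative=5, effect_size=3.0, seed=5,
))
sel = select_genes_ahp(ds, k=5)
print("selected genes:", ", ".join(sel.selected_gene_ids))

x = ds.matrix[sel.selected_index].T          # samples x genes
x = (x - x.mean(0)) / x.std(0, ddof=1)       # per-gene standardization
y = ds.labels.astype(float)

ga = GAConfig(population_size=10, generations=20, c_min=2, c_max=8, seed=0)
result = evolve(x, y, ga)
print(f"\nGA: initial mean rule count {result.initial_mean_rules:.1f} -> "
      f"best model {result.best_model.n_rules} rules "
      f"(fitness {result.best_fitness:.3f})")

model, trace = train_supervised(
    result.best_model, x, y, TrainConfig(epochs=60, seed=1)
)
print(f"gradient tuning: MSE {trace[0]:.4f} (epoch 1) -> "
      f"{min(trace):.4f} (best epoch)")

pred = (predict_batch(model, x) >= model.threshold).astype(int)
print(f"training accuracy: {np.mean(pred == ds.labels):.3f}")
print("\nrules (center norm | centroid | volume | weight):")
for j, r in enumerate(model.rules):
    print(f"  rule {j}: |m|={np.linalg.norm(r.centers):.2f}  "
          f"c={r.centroid:+.3f}  V={r.volume:.2f}  w={r.weight:.2f}")
print(
    "\nThe then-part centroids near 0 and 1 show the rules specializing\n"
    "to the two classes; the GA keeps the rule base small so the 59-sample\n"
    "training folds of a leave-one-out loop can still fit it."
)
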