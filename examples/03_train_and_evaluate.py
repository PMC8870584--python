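"""Subject-wise cross-validated classification of a strong-contrast cohort.

Runs the whole pipeline at CPU scale: 4 HC + 4 PD-OFF synthetic subjects
(30 s each, one channel), scalogram tiles, and the reduced CNN preset under
2-fold subject-wise cross-validation.  Prints per-fold and pooled accuracy,
sensitivity, specificity, AUC and quadratic weighted kappa.
"""

from scalonet import cross_validate
from scalonet.experiments import cohort_tiles
from scalonet.model import CnnSpec, TrainConfig

tiles = cohort_tiles(seed=3, n_hc=4, n_pd=4, duration_s=30.0)
print(f"{len(tiles)} tiles from {len(set(tiles.subjects))} subjects")

result = cross_validate(
    tiles, "hc-vs-off", k=2,
    cnn_spec=CnnSpec.reduced(),
    train_config=TrainConfig(batch_size=50, learning_rate=0.05, epochs=4,
                             seed=3, dtype="float32"),
    seed=3,
)

for i, m in enumerate(result.fold_metrics):
    print(f"fold {i}: accuracy {m.accuracy:.3f}  sensitivity "
          f"{m.sensitivity:.3f}  specificity {m.specificity:.3f}")
p = result.pooled
print(f"pooled: accuracy {p.accuracy:.3f}  sensitivity {p.sensitivity:.3f}  "
      f"specificity {p.specificity:.3f}  AUC {p.auc:.3f}  kappa {p.kappa:.3f}")
print("pooled confusion (rows = truth HC/PD, cols = prediction):")
print(p.confusion)
print("\nHeld-out subjects are classified from spectral structure alone;"
      "\nchance would be 0.5.")
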