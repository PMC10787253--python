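"""Augmentation mixes and the two-level evaluation of a tile classifier.

First, the three named augmentation mixes are applied to one tile under a
fixed seed (deterministic, so dataset previews are reproducible).  Then a
small prediction table for three slides is scored: one-vs-rest tile
metrics, majority voting per slide, and the intra-epoch early-stopping
trace that would govern training.
"""

import numpy as np
import pandas as pd

from histotile import (
    EarlyStopState,
    SynthParams,
    apply_augmentation,
    compose_mix,
    early_stop_update,
    generate_slide,
    hue_shift,
    majority_vote,
    read_region,
    slide_prediction_table,
    tile_metrics,
    validation_schedule,
)

pyr, _ = generate_slide(
    SynthParams(base_size=(256, 256), downsamples=(1, 2),
                nuclei_density_map=np.full((1, 1), 0.5), seed=2)
)
tile = read_region(pyr, 0, (64, 64), (128, 128)).pixels
for name in ("mix1", "mix2", "mix3"):
    spec = compose_mix(name, seed=5)
    out = apply_augmentation(tile, spec)
    print(f"{name}: ops={list(spec.ops)}, mean shift "
          f"{out.astype(float).mean() - tile.astype(float).mean():+.1f} channel units")
shifted = hue_shift(tile, 0.15)
print(f"hue-shift 0.15 turns: mean |delta| {np.abs(shifted.astype(int) - tile.astype(int)).mean():.1f}")

table = pd.DataFrame(
    {
        "slide_id": ["s0"] * 4 + ["s1"] * 4 + ["s2"] * 4,
        "tile_id": range(12),
        "true_label": ["GBM"] * 4 + ["GBM"] * 4 + ["BRCA"] * 4,
        "predicted_label": ["GBM", "GBM", "GBM", "BRCA",
                            "GBM", "BRCA", "BRCA", "BRCA",
                            "BRCA", "BRCA", "BRCA", "GBM"],
    }
)
report = tile_metrics(table, ["BRCA", "GBM"])
print(f"\ntile-level: accuracy {report.accuracy:.3f}, macro F1 {report.macro_f1:.3f}")
for cls, m in report.per_class.items():
    print(f"  {cls}: sens {m.sensitivity:.2f} spec {m.specificity:.2f} "
          f"prec {m.precision:.2f} F1 {m.f1:.2f}")

votes = majority_vote(table)
for sid, v in votes.items():
    print(f"slide {sid}: voted {v.label} {v.vote_counts}" + (" (tie)" if v.tie_flag else ""))
slide_report = tile_metrics(slide_prediction_table(table), ["BRCA", "GBM"])
print(f"slide-level accuracy after voting: {slide_report.accuracy:.3f}")

print(f"\nvalidation checkpoints for an 80-step epoch: {validation_schedule(80, 8)}")
state = EarlyStopState(patience=5)
scores = [0.70, 0.78, 0.81, 0.81, 0.80, 0.81, 0.79, 0.81]
for i, s in enumerate(scores, 1):
    state = early_stop_update(state, s)
    if state.stopped:
        print(f"early stopping fired at validation check {i} "
              f"(best score {state.best_score:.2f})")
        break
else:
    print(f"training continues; {state.non_improving} checks without improvement")
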