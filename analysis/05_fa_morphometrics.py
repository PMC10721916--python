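"""Adhesion segmentation, morphometrics, context features and maturity.

Renders a synthetic cell, segments adhesions from the acceptor channel,
measures equivalent-ellipse morphometrics and per-cell context features,
and trains/evaluates the PR-vs-SF maturity classifier on a synthetic
two-population feature set.
"""

from pathlib import Path

import numpy as np

from catchquant import (
    classify_fa_maturity,
    cytoplasm_mask,
    fa_context_features,
    fa_morphometrics,
    segment_fas,
)
from catchquant.synth import SceneSpec, gen_fret_scene, gen_maturity_features
from catchquant.workflows import random_fa_layout

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(4)
fas = random_fa_layout(rng, n_fas=7)
triplet, truth = gen_fret_scene(SceneSpec(fas=fas, seed=21))
labels = segment_fas(triplet.acceptor, truth["cell_mask"])
records = fa_morphometrics(labels, acceptor=triplet.acceptor)
records.to_csv(OUT / "fa_morphometrics.csv", index=False)
print(f"segmented {labels.max()} adhesions (planted {len(fas)})")
print(records[["id", "area", "fa_major", "fa_minor", "axis_ratio"]].round(2).to_string(index=False))

features = fa_context_features(records, truth["cell_mask"])
features.to_csv(OUT / "fa_context_features.csv", index=False)
cyto = cytoplasm_mask(labels, truth["cell_mask"])
print(f"cytoplasm mask: {cyto.sum()} px "
      f"({100 * cyto.sum() / truth['cell_mask'].sum():.0f}% of the cell)")

train_x, train_y = gen_maturity_features(n_per_class=150, seed=2)
n_train = int(0.8 * len(train_y))
_, model = classify_fa_maturity(train_x.iloc[:n_train], labels=train_y[:n_train], seed=0)
pred, _ = classify_fa_maturity(train_x.iloc[n_train:], model=model)
acc = (pred == train_y[n_train:]).mean()
print(f"maturity classifier held-out accuracy: {acc:.2f}")
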