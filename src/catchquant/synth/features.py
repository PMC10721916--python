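"""Synthetic PR/SF adhesion feature sets for classifier testing.

Two labelled populations drawn from distributions reflecting how the classes
differ morphometrically: mature stress-fiber-associated (SF) adhesions are
large, elongated, sparse, radially oriented and set back from the cell edge;
immature protrusion-associated (PR) adhesions are small, rounder, dense and
edge-proximal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gen_maturity_features(n_per_class: int = 100, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a labelled two-class feature table (columns match the classifier)."""
    rng = np.random.default_rng(seed)

    def _draw(n, area, axrat, d4, rel, rad, nce):
        return pd.DataFrame(
            {
                "area": rng.normal(*area, n).clip(5, None),
                "axis_ratio": rng.normal(*axrat, n).clip(1.0, None),
                "d4fa": rng.normal(*d4, n).clip(1.0, None),
                "theta_relative": rng.normal(*rel, n),
                "theta_radial": rng.normal(*rad, n),
                "d_nce": rng.normal(*nce, n).clip(0.0, 1.0),
            }
        )

    sf = _draw(n_per_class, area=(220, 40), axrat=(3.2, 0.5), d4=(40, 8),
               rel=(0.0, 0.25), rad=(0.0, 0.2), nce=(0.45, 0.1))
    pr = _draw(n_per_class, area=(60, 15), axrat=(1.5, 0.3), d4=(15, 4),
               rel=(0.0, 0.7), rad=(0.0, 0.7), nce=(0.12, 0.06))
    features = pd.concat([sf, pr], ignore_index=True)
    labels = np.array(["SF"] * n_per_class + ["PR"] * n_per_class)
    order = rng.permutation(len(labels))
    return features.iloc[order].reset_index(drop=True), labels[order]
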