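"""Optional report graphics: connectivity histogram and FISH bubble plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def connectivity_histogram(connect_max, ax=None, bins: int = 20):
    """Histogram of per-patient maximum connectivity (typically bimodal)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.asarray(connect_max, dtype=float), bins=bins, range=(0, 1),
            color="#4878a8", edgecolor="white")
    ax.set_xlabel("maximum spot membrane connectivity")
    ax.set_ylabel("patients")
    return ax


def fish_bubble_plot(patients: pd.DataFrame, ax=None):
    """HER2 and HER2/CEP17 against CEP17, bubble size = ConnectMax.

    Dashed guides mark polysomy (CEP17 > 3) and amplification
    (HER2 > 6, HER2/CEP17 > 2).  ``patients`` needs fish_her2,
    fish_cep17, fish_ratio and (optionally) connect_max columns.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    cep17 = patients["fish_cep17"].astype(float)
    her2 = patients["fish_her2"].astype(float)
    ratio = patients["fish_ratio"].astype(float)
    if "connect_max" in patients.columns:
        size = 20 + 280 * patients["connect_max"].fillna(0).astype(float)
    else:
        size = np.full(len(patients), 40.0)
    ax.scatter(cep17, her2, s=size, alpha=0.5, color="#3465a4", label="mean HER2/cell")
    ax.scatter(cep17, ratio, s=size, alpha=0.5, color="#e08020", label="HER2/CEP17")
    ax.axvline(3.0, color="black", linestyle="--", linewidth=1)
    ax.axhline(6.0, color="#3465a4", linestyle="--", linewidth=1)
    ax.axhline(2.0, color="#e08020", linestyle="--", linewidth=1)
    ax.set_xlabel("mean CEP17 per cell")
    ax.set_ylabel("mean HER2 per cell / HER2:CEP17 ratio")
    ax.legend(loc="upper left", frameon=False)
    return ax
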