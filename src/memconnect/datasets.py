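"""Bundled reference datasets.

Two small tables from a published breast-cancer tissue-microarray study of
HER2 scoring accompany the package:

* a 54-patient cohort with FISH results (HER2/CEP17 ratio, mean HER2 and
  CEP17 copies per cell) and the per-patient maximum HER2 IHC score under
  two visual evaluations (VE1max, VE2max) and digital analysis (DAmax) —
  every patient scored 2+/3+ by any rater and/or FISH ratio > 2 and/or
  CEP17 > 3;
* the six 3×3 rater cross-tabulations of that study: three at the spot
  level (575 spots) and three at the patient level (161 patients).

Decimal commas of the original tables were normalized to points and the
1/2/3 score coding is mapped onto the package's 0/1+, 2+, 3+ labels on
read.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .connectivity import SCORE_LABELS


def _data_path(name: str):
    return resources.files("memconnect.data").joinpath(name)


def load_fish_cohort() -> pd.DataFrame:
    """The 54-patient FISH/IHC reference cohort.

    Columns: patient_id, fish_ratio, fish_her2, fish_cep17, and the
    per-patient maximum scores ve1max, ve2max, damax as category labels.
    """
    with resources.as_file(_data_path("fish_reference_cohort.csv")) as path:
        raw = pd.read_csv(path)
    coded = {1: SCORE_LABELS[0], 2: SCORE_LABELS[1], 3: SCORE_LABELS[2]}
    return pd.DataFrame(
        {
            "patient_id": raw["line"].astype(str),
            "fish_ratio": raw["her2_cep17_ratio"].astype(float),
            "fish_her2": raw["her2_mean"].astype(float),
            "fish_cep17": raw["cep17_mean"].astype(float),
            "ve1max": raw["ve1max"].map(coded),
            "ve2max": raw["ve2max"].map(coded),
            "damax": raw["damax"].map(coded),
        }
    )


def load_agreement_tables() -> dict[tuple[str, str], np.ndarray]:
    """The six reference rater cross-tabulations.

    Returns a mapping from (comparison, level) — e.g. ("ve1_vs_da",
    "spot") — to a 3×3 integer array whose rows/columns follow the
    0/1+, 2+, 3+ category order.
    """
    with resources.as_file(_data_path("agreement_reference_tables.csv")) as path:
        raw = pd.read_csv(path)
    tables: dict[tuple[str, str], np.ndarray] = {}
    for (comparison, level), group in raw.groupby(["comparison", "level"], sort=False):
        ordered = group.set_index("row_category").loc[list(SCORE_LABELS)]
        tables[(comparison, level)] = ordered[["n_neg", "n_2plus", "n_3plus"]].to_numpy(
            dtype=int
        )
    return tables
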