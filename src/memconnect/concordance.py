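"""Agreement and FISH-concordance statistics for ordinal HER2 scores.

Per-spot scores from repeated visual evaluation (VE1, VE2) and digital
analysis (DA) are aggregated per patient as the maximum over that
patient's adequate spots (VE1max, VE2max, DAmax, ConnectMax) — the
preferred summary for tissue-microarray data where sampling is limited
and heterogeneity a concern.  Rater pairs are cross-tabulated into 3×3
ordinal contingency tables and summarized by linearly weighted kappa with
an asymptotic 95% confidence interval, plus raw percent agreement.  FISH
results (mean HER2 and CEP17 copies per cell and their ratio) enter as
tabular input; a patient is FISH-positive when HER2/CEP17 strictly
exceeds 2, and connectivity-vs-FISH association is tested by Pearson
correlation on (optionally) log-transformed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa

from .config import InputError
from .connectivity import SCORE_LABELS

logger = logging.getLogger(__name__)

#: ordinal coding of the merged HER2 categories
SCORE_CODES = {label: i for i, label in enumerate(SCORE_LABELS)}
#: 1/2/3 integer coding used by some published tables, mapped on read
NUMERIC_CODES = {1: 0, 2: 1, 3: 2}


def code_score(value) -> int:
    """Map a HER2 score to the internal ordinal coding 0/1/2.

    Accepts the category labels '0/1+', '2+', '3+' (also '0' and '1+' as
    negatives) or the 1/2/3 integer coding some published tables use;
    integer 0 is treated as negative.
    """
    if isinstance(value, str):
        value = value.strip()
        if value in SCORE_CODES:
            return SCORE_CODES[value]
        if value in {"0", "1+", "0/1"}:
            return 0
        try:
            value = int(value)
        except ValueError as exc:
            raise InputError(f"unrecognized HER2 score {value!r}") from exc
    value = int(value)
    if value == 0:
        return 0
    if value in NUMERIC_CODES:
        return NUMERIC_CODES[value]
    raise InputError(f"HER2 score out of range: {value}")


@dataclass
class PatientRecord:
    """Per-patient aggregate of spot scores and FISH values."""

    patient_id: str
    n_spots: int
    ve1max: str
    ve2max: str
    damax: str
    ve1range: int
    ve2range: int
    darange: int
    connect_max: Optional[float] = None
    fish_her2: Optional[float] = None
    fish_cep17: Optional[float] = None
    fish_ratio: Optional[float] = None


@dataclass
class AgreementResult:
    """Weighted kappa with asymptotic 95% CI and percent agreement."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    percent_agreement: float


def _aggregate(codes: np.ndarray, how: str) -> int:
    if how == "max":
        return int(codes.max())
    if how == "median":
        return int(round(np.median(codes)))
    if how == "mode":
        values, counts = np.unique(codes, return_counts=True)
        return int(values[counts.argmax()])
    raise InputError(f"unknown aggregation {how!r}")


def aggregate_patient(
    records: pd.DataFrame,
    min_spots: int = 2,
    aggregation: str = "max",
) -> Optional[PatientRecord]:
    """Summarize one patient's spot records; None when too few adequate spots.

    ``records`` needs columns patient_id, ve1, ve2, da (any accepted score
    coding), and optionally connectivity and adequate.  Scores are
    aggregated over adequate spots only.
    """
    if len(records) == 0:
        raise InputError("no spot records supplied")
    ids = records["patient_id"].unique()
    if len(ids) != 1:
        raise InputError(f"records span multiple patients: {ids}")
    if "adequate" in records.columns:
        records = records[records["adequate"].astype(bool)]
    if len(records) < min_spots:
        return None
    coded = {
        rater: records[rater].map(code_score).to_numpy()
        for rater in ("ve1", "ve2", "da")
    }
    connect_max = None
    if "connectivity" in records.columns:
        conn = pd.to_numeric(records["connectivity"], errors="coerce").dropna()
        if len(conn):
            connect_max = float(conn.max())
    return PatientRecord(
        patient_id=str(ids[0]),
        n_spots=int(len(records)),
        ve1max=SCORE_LABELS[_aggregate(coded["ve1"], aggregation)],
        ve2max=SCORE_LABELS[_aggregate(coded["ve2"], aggregation)],
        damax=SCORE_LABELS[_aggregate(coded["da"], aggregation)],
        ve1range=int(coded["ve1"].max() - coded["ve1"].min()),
        ve2range=int(coded["ve2"].max() - coded["ve2"].min()),
        darange=int(coded["da"].max() - coded["da"].min()),
        connect_max=connect_max,
    )


def aggregate_patients(
    spots: pd.DataFrame,
    min_spots: int = 2,
    aggregation: str = "max",
) -> pd.DataFrame:
    """Patient-level table from a spot-level table (one row per kept patient)."""
    rows = []
    for _, group in spots.groupby("patient_id", sort=True):
        record = aggregate_patient(group, min_spots=min_spots, aggregation=aggregation)
        if record is not None:
            rows.append(record.__dict__)
    return pd.DataFrame(rows)


def build_contingency(
    records: pd.DataFrame,
    rater_a: str,
    rater_b: str,
) -> np.ndarray:
    """3×3 cross-tabulation of two raters' ordinal scores.

    Records missing either score are skipped (and counted in the log).
    """
    a = records[rater_a]
    b = records[rater_b]
    valid = a.notna() & b.notna()
    skipped = int((~valid).sum())
    if skipped:
        logger.info("build_contingency: skipped %d records with missing scores", skipped)
    table = np.zeros((3, 3), dtype=int)
    for va, vb in zip(a[valid], b[valid]):
        table[code_score(va), code_score(vb)] += 1
    return table


def weighted_kappa(table: np.ndarray, weights: str = "linear") -> AgreementResult:
    """Weighted Cohen's kappa of a k×k ordinal contingency table.

    Uses disagreement weights ``|i - j| / (k - 1)`` ("linear"; "quadratic"
    squares them), the standard chance correction from the marginal
    products, and the large-sample variance for the 95% CI.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise InputError("contingency table is empty")
    if weights not in ("linear", "quadratic"):
        raise InputError(f"unknown kappa weighting {weights!r}")
    p = table / table.sum()
    k = table.shape[0]
    i, j = np.indices((k, k))
    w = 1.0 - (np.abs(i - j) / (k - 1)) ** (1 if weights == "linear" else 2)
    pe_w = float((np.outer(p.sum(axis=1), p.sum(axis=0)) * w).sum())
    if pe_w >= 1.0 - 1e-12:
        raise InputError("degenerate marginals: chance agreement is 1, kappa undefined")
    # the large-sample variance can be undefined on degenerate tables even
    # when kappa itself is well-defined; keep numpy quiet there
    with np.errstate(invalid="ignore", divide="ignore"):
        res = cohens_kappa(table, wt="linear" if weights == "linear" else "quadratic")
    return AgreementResult(
        kappa=float(res.kappa),
        se=float(np.sqrt(max(float(res.var_kappa), 0.0))),
        ci_low=float(res.kappa_low),
        ci_high=float(res.kappa_upp),
        percent_agreement=percent_agreement(table),
    )


def percent_agreement(table: np.ndarray) -> float:
    """Raw percent agreement: 100 × trace / total, to full precision."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        raise InputError("contingency table is empty")
    return float(100.0 * np.trace(table) / total)


def fish_positive(ratio: float) -> bool:
    """HER2 amplification by FISH: HER2/CEP17 ratio strictly above 2."""
    if ratio is None or (isinstance(ratio, float) and np.isnan(ratio)):
        raise InputError("missing FISH ratio")
    if ratio < 0:
        raise InputError("FISH ratio must be non-negative")
    return bool(ratio > 2.0)


def polysomy_flag(cep17: float) -> bool:
    """Chromosome-17 polysomy: mean CEP17 copies per cell strictly above 3."""
    if cep17 < 0:
        raise InputError("CEP17 count must be non-negative")
    return bool(cep17 > 3.0)


def amplification_flag(her2: float) -> bool:
    """Absolute HER2 amplification: mean HER2 copies per cell strictly above 6."""
    if her2 < 0:
        raise InputError("HER2 count must be non-negative")
    return bool(her2 > 6.0)


def fish_category_table(patients: pd.DataFrame, rater: str) -> pd.DataFrame:
    """FISH-positive proportion per HER2 score category of one rater.

    Returns one row per category with columns positives, total and
    percent (1 decimal; NaN for an empty category).  ``patients`` needs
    the rater column (any accepted coding) and fish_ratio.
    """
    if rater not in patients.columns:
        raise InputError(f"rater column {rater!r} missing")
    with_fish = patients[pd.to_numeric(patients["fish_ratio"], errors="coerce").notna()]
    rows = []
    codes = with_fish[rater].map(code_score)
    for cat, label in enumerate(SCORE_LABELS):
        members = with_fish[codes == cat]
        total = int(len(members))
        positives = int(sum(fish_positive(r) for r in members["fish_ratio"]))
        percent = round(100.0 * positives / total, 1) if total else float("nan")
        rows.append(
            {"category": label, "positives": positives, "total": total, "percent": percent}
        )
    return pd.DataFrame(rows)


def log_pearson(
    x: Sequence[float],
    y: Sequence[float],
    log_x: bool = True,
    log_y: bool = True,
) -> tuple[float, float]:
    """Pearson correlation of (optionally) log-transformed values.

    Returns (r, two-sided p).  Values to be logged must be strictly
    positive; offenders are reported in the error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 pairs")
    for name, values, flag in (("x", x, log_x), ("y", y, log_y)):
        if flag and (values <= 0).any():
            bad = values[values <= 0][:5]
            raise InputError(f"non-positive {name} values under log: {bad.tolist()}")
    if log_x:
        x = np.log(x)
    if log_y:
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
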