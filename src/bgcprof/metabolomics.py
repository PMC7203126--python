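"""Targeted metabolite fold changes with detection-limit conventions.

Amino-acid and metabolite comparisons between two strains follow these
conventions:

* replicate concentrations are summarised per (analyte, compartment,
  strain); replicates flagged below the detection limit carry no value
  and are dropped from mixed cells, while fully censored cells are
  "all below detection";
* when the analyte is detected in exactly one strain the log2 fold
  change is floored at a fixed magnitude (default +/-5) and no p-value
  is computed;
* otherwise the fold change is log2(test/reference) with a two-sided
  Welch t-test over detected replicates;
* markers follow the significance convention: p < alpha is
  "significant", alpha <= p < trend_alpha is a trend "(+)"/"(-)"
  depending on direction, larger p is "ns", floored entries are
  "floored".

The untargeted feature filter keeps m/z features whose log2 fold change
and normalized peak area both exceed fixed cuts, and quantities can be
normalised by cell dry weight to correct for growth differences.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import welch_test_from_samples
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds

__all__ = [
    "METABOLITE_COLUMNS",
    "validate_metabolite_table",
    "summarize_replicates",
    "floored_log2fc",
    "mark_significance",
    "analyze_metabolites",
    "filter_features",
    "normalize_by_dry_weight",
]

#: Long-format metabolite table columns: one row per replicate
#: measurement. ``value`` is empty when ``below_detection`` is set.
METABOLITE_COLUMNS = (
    "analyte",
    "compartment",
    "strain",
    "replicate",
    "value",
    "below_detection",
)


def validate_metabolite_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format metabolite table contract."""
    missing = set(METABOLITE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
    censored = table["below_detection"].astype(bool)
    if table.loc[censored, "value"].notna().any():
        raise ValueError("below-detection replicates must not carry a value")
    if table.loc[~censored, "value"].isna().any():
        raise ValueError("detected replicates must carry a value")
    return table


def summarize_replicates(
    values: Sequence[float | None],
    below_detection: Sequence[bool] | None = None,
) -> tuple[float, float, int, bool]:
    """Summarise one cell of replicate measurements.

    Censored replicates (``None``/NaN value or flagged) are treated as
    missing. Returns ``(mean, sd, n_detected, all_below_detection)``;
    mean and sd are NaN when everything is censored.
    """
    vals = np.asarray(
        [math.nan if v is None else float(v) for v in values], dtype=float
    )
    if vals.size == 0:
        raise ValueError("at least one replicate required")
    if below_detection is not None:
        flags = np.asarray(below_detection, dtype=bool)
        if flags.shape != vals.shape:
            raise ValueError("values and below_detection must align")
        vals = np.where(flags, math.nan, vals)
    detected = vals[~np.isnan(vals)]
    n = int(detected.size)
    if n == 0:
        return math.nan, math.nan, 0, True
    sd = float(detected.std(ddof=1)) if n > 1 else 0.0
    return float(detected.mean()), sd, n, False


def floored_log2fc(
    ref_mean: float | None,
    test_mean: float | None,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> tuple[float, bool] | None:
    """Log2 fold change of test over reference with the LOD floor.

    ``None`` (or NaN) means undetected. Both detected: plain
    log2(test/ref). Detected only in the reference: ``-lod_floor``;
    only in the test: ``+lod_floor``. Both undetected: returns ``None``
    (the analyte is excluded). The boolean marks a floored value.
    """

    def undetected(x: float | None) -> bool:
        return x is None or (isinstance(x, float) and math.isnan(x))

    ref_missing, test_missing = undetected(ref_mean), undetected(test_mean)
    if ref_missing and test_missing:
        return None
    if not ref_missing and ref_mean <= 0:
        raise ValueError("detected reference mean must be positive")
    if not test_missing and test_mean <= 0:
        raise ValueError("detected test mean must be positive")
    if test_missing:
        return -t.lod_floor, True
    if ref_missing:
        return t.lod_floor, True
    return math.log2(test_mean / ref_mean), False


def mark_significance(
    log2_fc: float,
    p_value: float,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
    floored: bool = False,
) -> str:
    """Marker for one analyte: significant, "(+)", "(-)", ns or floored."""
    if floored:
        return "floored"
    if math.isnan(p_value):
        return "ns"
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p_value < t.alpha:
        return "significant"
    if p_value < t.trend_alpha:
        return "trend_up" if log2_fc > 0 else "trend_down"
    return "ns"


def analyze_metabolites(
    table: pd.DataFrame,
    ref_strain: str,
    test_strain: str,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-analyte fold-change table comparing two strains.

    Parameters
    ----------
    table : DataFrame
        Long-format replicate table (see :data:`METABOLITE_COLUMNS`).
    ref_strain, test_strain : str
        Strain labels; fold changes are test relative to reference.

    Returns
    -------
    DataFrame with one row per (analyte, compartment) present in either
    strain, columns ``ref_mean``, ``test_mean``, ``log2_fc``,
    ``p_value``, ``marker``, ``floored``. Analytes undetected in both
    strains are excluded.
    """
    validate_metabolite_table(table)
    rows = []
    for (analyte, compartment), group in table.groupby(
        ["analyte", "compartment"], sort=True
    ):
        cells = {}
        for strain in (ref_strain, test_strain):
            sub = group.loc[group["strain"] == strain]
            if len(sub) == 0:
                raise ValueError(
                    f"{analyte}/{compartment}: no replicates for strain {strain}"
                )
            mean, sd, n, censored = summarize_replicates(
                sub["value"].tolist(), sub["below_detection"].astype(bool).tolist()
            )
            detected = sub.loc[~sub["below_detection"].astype(bool), "value"]
            cells[strain] = (mean, sd, n, censored, detected.to_numpy(dtype=float))
        ref_mean, _, ref_n, ref_cens, ref_vals = cells[ref_strain]
        test_mean, _, test_n, test_cens, test_vals = cells[test_strain]
        fc = floored_log2fc(
            None if ref_cens else ref_mean,
            None if test_cens else test_mean,
            t,
        )
        if fc is None:
            continue
        log2_fc, floored = fc
        if floored or ref_n < 2 or test_n < 2:
            p = math.nan
        elif ref_vals.std(ddof=1) == 0 and test_vals.std(ddof=1) == 0:
            p = 1.0 if ref_mean == test_mean else 0.0
        else:
            _, _, p = welch_test_from_samples(ref_vals, test_vals)
        rows.append(
            {
                "analyte": analyte,
                "compartment": compartment,
                "ref_mean": ref_mean,
                "test_mean": test_mean,
                "log2_fc": log2_fc,
                "p_value": p,
                "marker": mark_significance(log2_fc, p, t, floored),
                "floored": floored,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "compartment",
            "ref_mean",
            "test_mean",
            "log2_fc",
            "p_value",
            "marker",
            "floored",
        ],
    )


def filter_features(
    features: pd.DataFrame, t: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Keep untargeted m/z features passing both abundance cuts.

    A feature is kept when its log2 fold change strictly exceeds
    ``feature_min_fc`` and the larger of its two normalized peak areas
    strictly exceeds ``feature_min_area``. Expects columns ``mz``,
    ``retention``, ``area_a``, ``area_b``, ``log2_fc``.
    """
    if len(features) == 0:
        return features.copy()
    if (features[["area_a", "area_b"]] < 0).any().any():
        raise ValueError("peak areas must be nonnegative")
    keep = (features["log2_fc"] > t.feature_min_fc) & (
        features[["area_a", "area_b"]].max(axis=1) > t.feature_min_area
    )
    return features.loc[keep].copy()


def normalize_by_dry_weight(quantity: float, cdw: float) -> float:
    """Correct a peak area or titer for growth differences by dry weight."""
    if cdw <= 0:
        raise ValueError("cell dry weight must be positive")
    return quantity / cdw
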