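"""RPKM expression, two-strain differential expression and the BGC silencing screen.

The differential-expression conventions implemented here are those of a
chemostat RNA-seq comparison between a reference strain and a BGC
deletion strain:

* expression is quantified as RPKM (reads per kilobase of gene per
  million mapped reads), replicates averaged per strain;
* genes below an RPKM silence floor in *both* strains are excluded as
  potential genomic-DNA noise;
* genes silent in exactly one strain receive a capped log2 fold change
  of fixed magnitude (default +/-7) with the sign of the expressed
  strain, and no p-value;
* otherwise the fold change is log2(test/reference), and a two-sided
  Welch t-test (unequal variances) over replicate RPKM provides the
  p-value.

The silencing screen counts, per BGC core gene, the compendium
conditions in which its actin-relative expression falls below a
threshold; cores silent in at least ``screen_min_silent_conditions``
conditions are candidates for deletion, and the expressed remainder is
ranked for prioritization.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneCatalog
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds

__all__ = [
    "compute_rpkm",
    "average_replicates",
    "capped_log2fc",
    "welch_test",
    "welch_test_from_samples",
    "differential_expression",
    "call_de",
    "relative_to_actin",
    "screen_silent_core_genes",
    "prioritize_for_deletion",
]


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads Per Kilobase of gene per Million mapped reads.

    RPKM(g, s) = count(g, s) / ((length_bp(g)/1e3) * (library_size(s)/1e6)).

    Parameters
    ----------
    counts : DataFrame
        Raw counts, genes x samples.
    gene_lengths : Series
        Gene length in base pairs, indexed like ``counts``.
    library_sizes : Series, optional
        Total mapped reads per sample. Defaults to the column sums of
        ``counts``.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if set(counts.index) != set(gene_lengths.index):
        raise ValueError("gene sets of counts and gene_lengths differ")
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    sizes = pd.Series(library_sizes).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return counts.div(lengths / 1e3, axis=0).div(sizes / 1e6, axis=1)


def average_replicates(
    expr: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean expression per strain.

    ``groups`` maps sample id -> strain label; every strain must have at
    least one sample.
    """
    missing = set(groups) - set(expr.columns)
    if missing:
        raise ValueError(f"samples in groups absent from matrix: {sorted(missing)}")
    by_strain: dict[str, list[str]] = {}
    for sample, strain in groups.items():
        by_strain.setdefault(strain, []).append(sample)
    for strain, samples in by_strain.items():
        if not samples:
            raise ValueError(f"strain {strain} has no samples")
    return pd.DataFrame(
        {strain: expr[samples].mean(axis=1) for strain, samples in by_strain.items()}
    )


def capped_log2fc(
    mean_a: float,
    mean_b: float,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> float | None:
    """Capped log2 fold change of strain B relative to strain A.

    Returns ``None`` when both means are below the silence floor (the
    gene is excluded from the comparison). When exactly one side is
    silent the fixed cap ``t.fc_cap`` is assigned with the sign of the
    expressed side; otherwise log2(mean_b / mean_a) clamped to
    [-fc_cap, +fc_cap].
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("mean RPKM must be nonnegative")
    silent_a = mean_a < t.silent_rpkm
    silent_b = mean_b < t.silent_rpkm
    if silent_a and silent_b:
        return None
    if silent_a:
        return t.fc_cap
    if silent_b:
        return -t.fc_cap
    fc = math.log2(mean_b / mean_a)
    return min(max(fc, -t.fc_cap), t.fc_cap)


def welch_test(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
) -> tuple[float, float, float]:
    """Two-sided Welch t-test from summary statistics.

    Returns ``(t, df, p)`` with ``t = (mean2 - mean1) / sqrt(sd1^2/n1 +
    sd2^2/n2)`` and the Welch-Satterthwaite degrees of freedom. When
    both variances are zero and the means are equal the test degenerates
    to ``(0, inf, 1)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_test requires at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, math.inf, 1.0
        raise ValueError("both variances zero with unequal means")
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    res = stats.ttest_ind_from_stats(
        mean2, sd2, n2, mean1, sd1, n1, equal_var=False
    )
    return float(res.statistic), float(df), float(res.pvalue)


def welch_test_from_samples(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float, float]:
    """Welch t-test from raw replicate vectors (summary stats first)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    return welch_test(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def differential_expression(
    rpkm: pd.DataFrame,
    groups: Mapping[str, str],
    strains: tuple[str, str],
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene two-strain DE table with silence/cap conventions applied.

    Parameters
    ----------
    rpkm : DataFrame
        Per-replicate RPKM, genes x samples.
    groups : mapping
        Sample id -> strain label.
    strains : (reference, test)
        Orientation: fold changes are test relative to reference.

    Returns
    -------
    DataFrame indexed by gene with columns ``mean_rpkm_a``,
    ``mean_rpkm_b``, ``log2_fc``, ``p_value``, ``silent_a``,
    ``silent_b``, ``is_de``. Genes silent in both strains are excluded.
    Capped genes carry an undefined (NaN) p-value.
    """
    strain_a, strain_b = strains
    samples_a = [s for s, g in groups.items() if g == strain_a]
    samples_b = [s for s, g in groups.items() if g == strain_b]
    if not samples_a or not samples_b:
        raise ValueError("each strain needs at least one sample")
    means = average_replicates(rpkm, groups)
    rows: list[dict[str, object]] = []
    for gene in rpkm.index:
        mean_a = float(means.at[gene, strain_a])
        mean_b = float(means.at[gene, strain_b])
        fc = capped_log2fc(mean_a, mean_b, t)
        if fc is None:  # silent in both strains: potential gDNA noise
            continue
        silent_a = mean_a < t.silent_rpkm
        silent_b = mean_b < t.silent_rpkm
        if silent_a or silent_b or len(samples_a) < 2 or len(samples_b) < 2:
            p = math.nan
        else:
            a = rpkm.loc[gene, samples_a].to_numpy(dtype=float)
            b = rpkm.loc[gene, samples_b].to_numpy(dtype=float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() != b.mean():
                p = 0.0
            else:
                _, _, p = welch_test_from_samples(a, b)
        rows.append(
            {
                "gene_id": gene,
                "mean_rpkm_a": mean_a,
                "mean_rpkm_b": mean_b,
                "log2_fc": fc,
                "p_value": p,
                "silent_a": silent_a,
                "silent_b": silent_b,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "mean_rpkm_a",
            "mean_rpkm_b",
            "log2_fc",
            "p_value",
            "silent_a",
            "silent_b",
        ],
    ).set_index("gene_id")
    return call_de(table, t)


def call_de(
    table: pd.DataFrame, t: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Set the ``is_de`` flag on a DE table.

    A gene is differentially expressed when |log2 FC| strictly exceeds
    ``de_min_abs_fc`` and either p < alpha or the p-value is undefined
    because one side is silent (the cap alone carries the call).
    """
    table = table.copy()
    fc_ok = table["log2_fc"].abs() > t.de_min_abs_fc
    p = table["p_value"]
    table["is_de"] = fc_ok & (p.isna() | (p < t.alpha))
    return table


def relative_to_actin(expr: float, actin_expr: float) -> float:
    """Expression level as a fraction of the actin reference level."""
    if actin_expr <= 0:
        raise ValueError("actin expression must be positive")
    return expr / actin_expr


def screen_silent_core_genes(
    condition_expr: pd.DataFrame,
    cat: GeneCatalog,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Silencing screen over BGC core genes across compendium conditions.

    A core gene counts as "not expressed" in a condition when its
    actin-relative expression there is below ``t.actin_rel_silent``; it
    is called silent overall when that happens in at least
    ``t.screen_min_silent_conditions`` conditions.

    Parameters
    ----------
    condition_expr : DataFrame
        Expression levels, genes x conditions; must contain the actin
        reference gene of the catalog.
    cat : GeneCatalog
        Catalog with core genes flagged.

    Returns
    -------
    DataFrame indexed by core gene id with columns
    ``n_conditions_silent``, ``n_conditions_total``, ``is_silent``,
    ``median_actin_rel``, in genome order.
    """
    actin = cat.actin_gene
    if actin is None or actin.gene_id not in condition_expr.index:
        raise ValueError("actin reference gene missing from expression matrix")
    actin_row = condition_expr.loc[actin.gene_id]
    if (actin_row <= 0).any():
        raise ValueError("actin expression must be positive in every condition")
    rows = []
    for gene in cat.core_genes():
        if gene.gene_id not in condition_expr.index:
            raise ValueError(f"core gene {gene.gene_id} missing from matrix")
        rel = condition_expr.loc[gene.gene_id] / actin_row
        n_silent = int((rel < t.actin_rel_silent).sum())
        rows.append(
            {
                "gene_id": gene.gene_id,
                "bgc_id": gene.bgc_id,
                "n_conditions_silent": n_silent,
                "n_conditions_total": int(rel.size),
                "is_silent": n_silent >= t.screen_min_silent_conditions,
                "median_actin_rel": float(rel.median()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "bgc_id",
            "n_conditions_silent",
            "n_conditions_total",
            "is_silent",
            "median_actin_rel",
        ],
    ).set_index("gene_id")


def prioritize_for_deletion(screen: pd.DataFrame) -> pd.DataFrame:
    """Non-silent core genes ranked by median actin-relative expression.

    The most robustly expressed cores rank first: these drive the
    strain's secondary-metabolite burden and are the deletion candidates.
    """
    active = screen.loc[~screen["is_silent"]].copy()
    return active.sort_values("median_actin_rel", ascending=False)
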