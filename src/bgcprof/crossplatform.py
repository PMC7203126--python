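"""Cross-platform z-scores, cluster footprints and category enrichment.

The central statistic compares one RNA-seq log2 fold change (the "raw
score") against the population of log2 fold changes the same gene shows
across a compendium of microarray high-versus-low production contrasts:

    z(g) = (raw_fc(g) - mean(pop_fc(g))) / sd(pop_fc(g))

with the sample (n-1) standard deviation. Genes must be present in at
least half of the compendium datasets to be scored. |z| < 0.2 marks
expression behaviour already explained by a reduced production burden;
|z| > 1.25 marks genuinely divergent behaviour. Runs of consecutive
divergent genes of one sign along a contig are the genomic footprint of
a deleted (or co-regulated) gene cluster.

A simulation-based alternative to the fixed divergence cutoff is
provided: sampling normal pseudo-populations per gene and recording the
distribution of null z-scores yields the threshold with a chosen false
positive rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import GeneCatalog
from .thresholds import DEFAULT_THRESHOLDS, AnalysisThresholds

__all__ = [
    "Compendium",
    "coverage_filter",
    "compute_z",
    "classify_band",
    "zmap",
    "band_counts",
    "calibrate_threshold",
    "detect_clusters",
    "divergent_singletons",
    "enrich_hypergeometric",
    "bh_adjust",
]

BANDS = ("similar", "altered", "divergent_pos", "divergent_neg", "uncovered")


@dataclass(frozen=True)
class Compendium:
    """Per-dataset per-gene log2 fold changes with missingness.

    ``values`` is a genes x datasets DataFrame; NaN marks a gene absent
    from a dataset.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("compendium needs at least one dataset")

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_datasets(self) -> int:
        return self.values.shape[1]

    def coverage(self) -> pd.Series:
        """Fraction of datasets each gene is present in."""
        return self.values.notna().mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Compendium):
            return NotImplemented
        if self.values.shape != other.values.shape:
            return False
        if list(self.values.index) != list(other.values.index):
            return False
        if list(self.values.columns) != list(other.values.columns):
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return bool(np.array_equal(a, b, equal_nan=True))


def coverage_filter(
    row: Sequence[float] | pd.Series,
    n_datasets: int | None = None,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True when the gene is present in at least ``coverage_min`` of datasets."""
    values = np.asarray(row, dtype=float)
    total = n_datasets if n_datasets is not None else values.size
    if total == 0:
        return False
    return bool(np.count_nonzero(~np.isnan(values)) / total >= t.coverage_min)


def compute_z(
    raw_fc: float, population_fcs: Sequence[float]
) -> tuple[float, float, int, float | None]:
    """Core z computation for one gene.

    Returns ``(pop_mean, pop_sd, n_covered, z)``; ``z`` is ``None`` when
    fewer than two population values exist or their sample SD is zero.
    Negative z means the raw score lies below the population mean.
    """
    pop = np.asarray(
        [v for v in np.asarray(population_fcs, dtype=float) if not math.isnan(v)]
    )
    n = pop.size
    if n < 2:
        return (float(pop.mean()) if n else math.nan, math.nan, n, None)
    mean = float(pop.mean())
    sd = float(pop.std(ddof=1))
    if sd < 1e-12 * max(1.0, abs(mean)):  # constant population up to rounding
        return mean, 0.0, n, None
    return mean, sd, n, (raw_fc - mean) / sd


def classify_band(z: float, t: AnalysisThresholds = DEFAULT_THRESHOLDS) -> str:
    """Band label for a defined z-score.

    Strict at both boundaries: |z| < z_similar is "similar", |z| >
    z_divergent is divergent (signed); everything between, ties
    included, is "altered".
    """
    if math.isnan(z):
        raise ValueError("z must be defined")
    if abs(z) < t.z_similar:
        return "similar"
    if z > t.z_divergent:
        return "divergent_pos"
    if z < -t.z_divergent:
        return "divergent_neg"
    return "altered"


def zmap(
    de_table: pd.DataFrame,
    compendium: Compendium,
    cat: GeneCatalog,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
    de_only: bool = True,
) -> pd.DataFrame:
    """Per-gene z-scores in genome order.

    Parameters
    ----------
    de_table : DataFrame
        Output of :func:`bgcprof.expression.differential_expression`.
    compendium : Compendium
        Microarray contrast population.
    cat : GeneCatalog
        Supplies contig and ordinal position of every gene.
    de_only : bool
        Score only genes flagged ``is_de`` (the raw scores of interest);
        others are reported uncovered.

    Returns
    -------
    DataFrame indexed by gene id in catalog order with columns
    ``contig``, ``position``, ``raw_fc``, ``pop_mean``, ``pop_sd``,
    ``n_covered``, ``z``, ``band``. Genes failing the coverage filter or
    without a defined z carry band "uncovered".
    """
    rows = []
    position = 0
    for gene in cat:
        position += 1
        gid = gene.gene_id
        raw_fc = math.nan
        pop_mean = pop_sd = math.nan
        n_covered = 0
        z: float | None = None
        band = "uncovered"
        eligible = gid in de_table.index and (
            not de_only or bool(de_table.at[gid, "is_de"])
        )
        if gid in compendium.values.index:
            pop = compendium.values.loc[gid].to_numpy(dtype=float)
            n_covered = int(np.count_nonzero(~np.isnan(pop)))
            if eligible:
                raw_fc = float(de_table.at[gid, "log2_fc"])
                if coverage_filter(pop, compendium.n_datasets, t):
                    pop_mean, pop_sd, n_covered, z = compute_z(raw_fc, pop)
                    if z is not None:
                        band = classify_band(z, t)
        elif eligible:
            raw_fc = float(de_table.at[gid, "log2_fc"])
        rows.append(
            {
                "gene_id": gid,
                "contig": gene.contig,
                "position": position,
                "raw_fc": raw_fc,
                "pop_mean": pop_mean,
                "pop_sd": pop_sd,
                "n_covered": n_covered,
                "z": math.nan if z is None else z,
                "band": band,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def band_counts(zmap_table: pd.DataFrame) -> pd.Series:
    """Number of genes in each band (covered bands plus "uncovered")."""
    return zmap_table["band"].value_counts().reindex(BANDS, fill_value=0)


def calibrate_threshold(
    per_gene_stats: Sequence[tuple[float, float, int]],
    target_fpr: float,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Divergence threshold with a chosen false positive rate.

    For every gene ``(pop_mean, pop_sd, n_covered)`` a null experiment
    is simulated: a pseudo-population of ``n_covered`` normal draws
    yields a sample mean and sample SD, one additional draw from the
    same normal plays the raw score, and the null z-score is their
    studentized distance. The threshold is the two-sided ``1 -
    target_fpr`` quantile of |z| pooled over genes and simulations.

    The pseudo-population is realised through the exact sampling
    distributions of its sufficient statistics (sample mean ~ Normal,
    sample SD ~ scaled chi), which is distributionally identical to
    materialising the draws and keeps large ``n_covered`` cheap.
    Deterministic given ``seed``.
    """
    if not 0 < target_fpr <= 1:
        raise ValueError("target_fpr must be in (0, 1]")
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if target_fpr == 1.0:
        return 0.0
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    for mean, sd, n in per_gene_stats:
        if sd <= 0:
            warnings.warn(
                f"skipping gene with nonpositive population SD ({sd})", stacklevel=2
            )
            continue
        if n < 2:
            warnings.warn(
                f"skipping gene with n_covered={n} < 2", stacklevel=2
            )
            continue
        sample_mean = rng.normal(mean, sd / math.sqrt(n), size=n_sims)
        sample_sd = sd * np.sqrt(rng.chisquare(n - 1, size=n_sims) / (n - 1))
        raw = rng.normal(mean, sd, size=n_sims)
        pooled.append(np.abs((raw - sample_mean) / sample_sd))
    if not pooled:
        raise ValueError("no usable genes for calibration")
    return float(np.quantile(np.concatenate(pooled), 1.0 - target_fpr))


def detect_clusters(
    zmap_table: pd.DataFrame,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
    min_run: int = 3,
) -> pd.DataFrame:
    """Maximal runs of consecutive concordant divergent genes per contig.

    A cluster is >= ``min_run`` consecutive covered genes on one contig
    whose z-scores all exceed ``+z_divergent`` (sign ``+``) or all fall
    below ``-z_divergent`` (sign ``-``). Uncovered genes break runs and
    runs never span contig boundaries.

    Returns a DataFrame with columns ``contig``, ``first_gene``,
    ``last_gene``, ``first_position``, ``last_position``, ``n_genes``,
    ``sign``, ``mean_z``.
    """
    if min_run < 1:
        raise ValueError("min_run must be at least 1")
    gene_ids = list(zmap_table.index)
    contigs = zmap_table["contig"].tolist()
    positions = zmap_table["position"].tolist()
    zs = zmap_table["z"].to_numpy(dtype=float) if len(zmap_table) else np.array([])

    calls: list[dict[str, object]] = []
    run: list[int] = []  # row indices of the current run
    run_sign = 0

    def flush() -> None:
        if len(run) >= min_run:
            calls.append(
                {
                    "contig": contigs[run[0]],
                    "first_gene": gene_ids[run[0]],
                    "last_gene": gene_ids[run[-1]],
                    "first_position": int(positions[run[0]]),
                    "last_position": int(positions[run[-1]]),
                    "n_genes": len(run),
                    "sign": "+" if run_sign > 0 else "-",
                    "mean_z": float(zs[run].mean()),
                }
            )

    for i in range(len(gene_ids)):
        z = zs[i]
        if math.isnan(z):
            sign = 0
        elif z > t.z_divergent:
            sign = 1
        elif z < -t.z_divergent:
            sign = -1
        else:
            sign = 0
        contig_break = bool(run) and contigs[i] != contigs[run[-1]]
        if sign != run_sign or sign == 0 or contig_break:
            flush()
            run, run_sign = [], 0
        if sign != 0:
            run.append(i)
            run_sign = sign
    flush()
    return pd.DataFrame(
        calls,
        columns=[
            "contig",
            "first_gene",
            "last_gene",
            "first_position",
            "last_position",
            "n_genes",
            "sign",
            "mean_z",
        ],
    )


def divergent_singletons(
    zmap_table: pd.DataFrame,
    clusters: pd.DataFrame,
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Divergent genes outside any cluster call.

    Single-gene footprints (e.g. a deleted stand-alone synthetase) are
    reported here rather than as clusters.
    """
    in_cluster: set[str] = set()
    for call in clusters.itertuples():
        mask = (
            (zmap_table["contig"] == call.contig)
            & (zmap_table["position"] >= call.first_position)
            & (zmap_table["position"] <= call.last_position)
        )
        in_cluster.update(zmap_table.index[mask])
    divergent = zmap_table["band"].isin(["divergent_pos", "divergent_neg"])
    return zmap_table.loc[divergent & ~zmap_table.index.isin(in_cluster)]


def enrich_hypergeometric(
    gene_set: Sequence[str],
    background: Sequence[str],
    category_annotation: Mapping[str, frozenset[str] | set[str]],
    t: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Upper-tail hypergeometric category enrichment with BH correction.

    For each category with K annotated genes in a background of N, and k
    of the n-gene query set annotated, p = P(X >= k) for X ~
    Hypergeometric(N, K, n). q-values are Benjamini-Hochberg over all
    tested categories; ``enriched`` flags q < alpha.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValueError("background must not be empty")
    gene_set = list(dict.fromkeys(gene_set))
    extra = set(gene_set) - set(background)
    if extra:
        raise ValueError(f"gene set not contained in background: {sorted(extra)[:5]}")
    n_bg, n_set = len(background), len(gene_set)
    categories = sorted({c for g in background for c in category_annotation.get(g, ())})
    rows = []
    for cat in categories:
        members = {g for g in background if cat in category_annotation.get(g, ())}
        k_bg = len(members)
        k_set = len(members.intersection(gene_set))
        p = float(stats.hypergeom.sf(k_set - 1, n_bg, k_bg, n_set))
        rows.append(
            {
                "category": cat,
                "k_in_set": k_set,
                "k_in_background": k_bg,
                "n_set": n_set,
                "n_background": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "category",
            "k_in_set",
            "k_in_background",
            "n_set",
            "n_background",
            "p_value",
        ],
    )
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].tolist())
        result["enriched"] = result["q_value"] < t.alpha
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    return result


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]
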