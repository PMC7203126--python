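"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a two-strain chemostat RNA-seq design in a
filamentous fungus with annotated biosynthetic gene clusters (BGCs):

* a gene catalog over a handful of contigs, with planted BGCs (one
  flagged core synthase each), a gamma-actin reference gene, and flat
  functional category labels;
* negative-binomial count matrices for a reference strain and a
  deletion strain in which the deleted BGC genes are exactly zero and a
  set of genome-wide "burden" genes respond to the relieved production
  burden;
* a compendium of microarray-style per-dataset log2 fold changes from
  high-versus-low production contrasts, with per-value missingness —
  burden genes respond there too, so their cross-platform z-scores stay
  near zero while deleted clusters diverge;
* a 26-condition expression matrix for the core-gene silencing screen;
* replicate metabolite concentration tables with lognormal noise and
  detection-limit censoring of extracellular values;
* qPCR plates realising chosen fold changes through the ddCt identity.

One global integer seed drives an independent substream per generator
(numpy ``SeedSequence`` spawn keys), so stages are reproducible when
run separately.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, GeneRecord
from .crossplatform import Compendium
from .metabolomics import METABOLITE_COLUMNS
from .qpcr import QpcrPlate

__all__ = [
    "BgcSpec",
    "MetaboliteSpec",
    "SynthConfig",
    "StrainSpec",
    "CATEGORY_VOCABULARY",
    "default_config",
    "generate_genome",
    "generate_counts",
    "generate_compendium",
    "compendium_latents",
    "generate_condition_expression",
    "generate_metabolite_table",
    "generate_qpcr_plate",
]

#: Flat functional-category vocabulary (no hierarchy); enrichment only
#: needs opaque labels.
CATEGORY_VOCABULARY = (
    "metabolism",
    "amino acid metabolism",
    "secondary metabolism",
    "energy",
    "transport",
    "transcription",
    "protein synthesis",
    "protein fate",
    "stress response",
    "cell cycle",
    "signal transduction",
    "autophagy",
    "unclassified",
)

# substream keys: one per generator so stages stay independently reproducible
_STREAMS = {
    "genome": 1,
    "baseline": 2,
    "burden": 3,
    "counts": 4,
    "compendium": 5,
    "screen": 6,
    "metabolites": 7,
    "qpcr": 8,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream], *extra])


def _label_key(label: str) -> int:
    # stable 31-bit key for strain labels in substream seeds
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class BgcSpec:
    """A planted BGC: genes [start, start+n) on one contig, one core."""

    contig_index: int
    start_gene_index: int  # index within the contig's gene list
    n_genes: int
    core_gene_index: int = 0  # offset of the core gene inside the cluster

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("BGC must contain at least one gene")
        if not 0 <= self.core_gene_index < self.n_genes:
            raise ValueError("core_gene_index must lie inside the cluster")


@dataclass(frozen=True)
class MetaboliteSpec:
    """True mean concentrations for one analyte in one compartment.

    Units are nM for the extracellular compartment and uM per g cell
    dry weight intracellularly.
    """

    analyte: str
    compartment: str
    ref_mean: float
    test_mean: float

    def __post_init__(self) -> None:
        if self.compartment not in {"intracellular", "extracellular"}:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.ref_mean <= 0 or self.test_mean <= 0:
            raise ValueError("true means must be positive")


def _default_metabolite_specs() -> tuple[MetaboliteSpec, ...]:
    """Amino-acid panel emulating a chemostat comparison.

    Methionine drops and is lost from the supernatant, alanine is lost
    extracellularly while unchanged inside, aromatic amino acids rise
    about half a log2 unit, histidine rises moderately and cysteine and
    valine stay flat intracellularly. Extracellular true means below
    the detection limit realise the censoring pathway.
    """
    return (
        MetaboliteSpec("methionine", "intracellular", 0.09, 0.02),
        MetaboliteSpec("methionine", "extracellular", 0.2, 0.002),
        MetaboliteSpec("alanine", "intracellular", 32.5, 32.5),
        MetaboliteSpec("alanine", "extracellular", 6.5, 0.002),
        MetaboliteSpec("cysteine", "intracellular", 0.8, 0.8),
        MetaboliteSpec("cysteine", "extracellular", 2.3, 1.7),
        MetaboliteSpec("valine", "intracellular", 3.2, 3.2),
        MetaboliteSpec("histidine", "intracellular", 1.2, 1.7),
        MetaboliteSpec("tryptophan", "intracellular", 0.078, 0.11),
        MetaboliteSpec("tyrosine", "intracellular", 0.297, 0.42),
        MetaboliteSpec("phenylalanine", "intracellular", 0.389, 0.55),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the emulated study design.

    ``n_datasets`` doubles as the number of compendium contrasts and of
    silencing-screen conditions (26). ``dispersion`` is the negative
    binomial size parameter k with variance mean + mean^2/k.
    """

    n_genes: int = 2000
    n_contigs: int = 8
    gene_length_range: tuple[int, int] = (500, 5000)
    bgc_specs: tuple[BgcSpec, ...] = (
        BgcSpec(0, 40, 5, 2),
        BgcSpec(1, 25, 6, 0),
        BgcSpec(2, 60, 7, 3),
        BgcSpec(3, 10, 3, 1),
    )
    n_burden_genes: int = 100
    burden_effect: float = 1.0
    baseline_mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float = 10.0
    n_datasets: int = 26
    missing_rate: float = 0.3
    compendium_sigma_range: tuple[float, float] = (0.3, 0.8)
    lod_nm: float = 0.02
    seed: int = 0
    # extensions beyond the core design ------------------------------------
    ref_library_size: float = 2.0e6  # library size at which baselines apply
    screen_silent_fraction: float = 17 / 49  # silent cores in the screen
    metabolite_specs: tuple[MetaboliteSpec, ...] = field(
        default_factory=_default_metabolite_specs
    )
    metabolite_cv: float = 0.10
    n_metab_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_contigs < 1 or self.n_contigs > self.n_genes:
            raise ValueError("need 1 <= n_contigs <= n_genes")
        if self.gene_length_range[0] < 1 or (
            self.gene_length_range[0] > self.gene_length_range[1]
        ):
            raise ValueError("invalid gene_length_range")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean_range[0] <= 0 or (
            self.baseline_mean_range[0] > self.baseline_mean_range[1]
        ):
            raise ValueError("invalid baseline_mean_range")
        if self.compendium_sigma_range[0] <= 0 or (
            self.compendium_sigma_range[0] > self.compendium_sigma_range[1]
        ):
            raise ValueError("invalid compendium_sigma_range")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be at least 1")
        if self.lod_nm <= 0:
            raise ValueError("lod_nm must be positive")
        if not 0 <= self.screen_silent_fraction <= 1:
            raise ValueError("screen_silent_fraction must lie in [0, 1]")
        # BGC regions must fit their contig and not overlap
        sizes = _contig_sizes(self.n_genes, self.n_contigs)
        seen: dict[int, list[tuple[int, int]]] = {}
        for spec in self.bgc_specs:
            if not 0 <= spec.contig_index < self.n_contigs:
                raise ValueError(f"BGC contig index {spec.contig_index} out of range")
            lo, hi = spec.start_gene_index, spec.start_gene_index + spec.n_genes
            if lo < 0 or hi > sizes[spec.contig_index]:
                raise ValueError(
                    f"BGC [{lo}, {hi}) exceeds contig {spec.contig_index} "
                    f"bounds (size {sizes[spec.contig_index]})"
                )
            for a, b in seen.setdefault(spec.contig_index, []):
                if lo < b and a < hi:
                    raise ValueError("BGC regions overlap")
            seen[spec.contig_index].append((lo, hi))


@dataclass(frozen=True)
class StrainSpec:
    """One strain of the two-strain RNA-seq design."""

    strain_id: str
    deleted_bgc_ids: frozenset[str] = frozenset()
    n_replicates: int = 3
    library_size: float = 2.0e6

    def __post_init__(self) -> None:
        object.__setattr__(self, "deleted_bgc_ids", frozenset(self.deleted_bgc_ids))
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def default_config(**overrides) -> SynthConfig:
    """The desk-scale study design with optional field overrides."""
    return SynthConfig(**overrides)


def _contig_sizes(n_genes: int, n_contigs: int) -> list[int]:
    base, extra = divmod(n_genes, n_contigs)
    return [base + (1 if i < extra else 0) for i in range(n_contigs)]


def bgc_id_for(index: int) -> str:
    return f"BGC{index + 1:02d}"


def generate_genome(config: SynthConfig) -> GeneCatalog:
    """Gene catalog with planted BGCs, categories and an actin reference."""
    rng = _rng(config.seed, "genome")
    sizes = _contig_sizes(config.n_genes, config.n_contigs)
    lo, hi = config.gene_length_range
    # resolve BGC membership as (contig, within-contig index) -> (bgc, core)
    bgc_at: dict[tuple[int, int], tuple[str, bool]] = {}
    for j, spec in enumerate(config.bgc_specs):
        label = bgc_id_for(j)
        for k in range(spec.n_genes):
            bgc_at[(spec.contig_index, spec.start_gene_index + k)] = (
                label,
                k == spec.core_gene_index,
            )
    genes: list[GeneRecord] = []
    gene_no = 0
    non_bgc_positions: list[int] = []
    records: list[dict] = []
    for ci, size in enumerate(sizes):
        pos = 1
        for gi in range(size):
            length = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(100, 1000))
            start = pos
            end = start + length - 1
            pos = end + gap
            bgc_id, is_core = bgc_at.get((ci, gi), (None, False))
            if bgc_id is None:
                non_bgc_positions.append(gene_no)
            records.append(
                {
                    "gene_id": f"gene{gene_no:05d}",
                    "contig": f"contig{ci + 1:02d}",
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "bgc_id": bgc_id,
                    "is_core": is_core,
                }
            )
            gene_no += 1
    actin_pos = int(rng.choice(non_bgc_positions)) if non_bgc_positions else -1
    vocab = np.array(CATEGORY_VOCABULARY)
    for i, rec in enumerate(records):
        n_cat = int(rng.integers(1, 4))
        cats = set(rng.choice(vocab, size=n_cat, replace=False).tolist())
        if rec["bgc_id"] is not None:
            cats.add("secondary metabolism")
        if i == actin_pos:
            cats.add("cytoskeleton")
        genes.append(
            GeneRecord(
                categories=frozenset(cats),
                is_actin=(i == actin_pos),
                **rec,
            )
        )
    return GeneCatalog(genes)


def baseline_means(cat: GeneCatalog, config: SynthConfig) -> pd.Series:
    """Per-gene expected counts at the reference library size.

    Log-uniform over ``baseline_mean_range``; BGC members draw from the
    top decade of the range, emulating the highly expressed clusters
    that motivate deletion.
    """
    rng = _rng(config.seed, "baseline")
    lo, hi = config.baseline_mean_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    draws = np.exp(rng.uniform(log_lo, log_hi, size=len(cat)))
    bgc_lo = max(lo, hi / 10.0)
    bgc_draws = np.exp(
        rng.uniform(math.log(bgc_lo), log_hi, size=len(cat))
    )
    in_bgc = np.array([g.bgc_id is not None for g in cat])
    return pd.Series(
        np.where(in_bgc, bgc_draws, draws), index=cat.gene_ids, name="baseline_mean"
    )


def burden_genes(cat: GeneCatalog, config: SynthConfig) -> list[str]:
    """Genes responding to the relieved production burden (outside BGCs)."""
    rng = _rng(config.seed, "burden")
    candidates = [g.gene_id for g in cat if g.bgc_id is None and not g.is_actin]
    n = min(config.n_burden_genes, len(candidates))
    picked = rng.choice(np.array(candidates), size=n, replace=False)
    return sorted(picked.tolist())


def generate_counts(
    cat: GeneCatalog, spec: StrainSpec, config: SynthConfig
) -> pd.DataFrame:
    """Negative-binomial count matrix for one strain.

    Expected counts scale the per-gene baseline by ``library_size /
    ref_library_size``. Genes of deleted BGCs are exactly zero in all
    replicates; burden genes shift by ``burden_effect`` log2 units in
    the deletion strain. Variance is mean + mean^2/dispersion.
    """
    means = baseline_means(cat, config) * (
        spec.library_size / config.ref_library_size
    )
    if spec.deleted_bgc_ids:
        unknown = spec.deleted_bgc_ids - set(cat.bgc_ids())
        if unknown:
            raise ValueError(f"deleted BGCs absent from catalog: {sorted(unknown)}")
        deleted = np.array([g.bgc_id in spec.deleted_bgc_ids for g in cat])
        means = means.where(~deleted, 0.0)
        shift = 2.0**config.burden_effect
        burden = set(burden_genes(cat, config))
        means = means * np.array(
            [shift if gid in burden else 1.0 for gid in cat.gene_ids]
        )
    rng = _rng(config.seed, "counts", _label_key(spec.strain_id))
    k = config.dispersion
    m = means.to_numpy()[:, None]
    shape = (len(cat), spec.n_replicates)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(m > 0, k / (k + m), 1.0)
    counts = rng.negative_binomial(k, p, size=shape)
    counts = np.where(m > 0, counts, 0)
    columns = [f"{spec.strain_id}_r{i + 1}" for i in range(spec.n_replicates)]
    return pd.DataFrame(counts, index=cat.gene_ids, columns=columns)


def compendium_latents(cat: GeneCatalog, config: SynthConfig) -> pd.DataFrame:
    """Latent per-gene (mu, sigma) behind the compendium contrasts.

    Burden genes have mu equal to ``burden_effect`` (they respond to
    the production contrast on both platforms); all other genes are
    null (mu = 0). Sigma is uniform over ``compendium_sigma_range``.
    """
    rng = _rng(config.seed, "compendium")
    sigma = rng.uniform(*config.compendium_sigma_range, size=len(cat))
    burden = set(burden_genes(cat, config))
    mu = np.array(
        [config.burden_effect if gid in burden else 0.0 for gid in cat.gene_ids]
    )
    return pd.DataFrame({"mu": mu, "sigma": sigma}, index=cat.gene_ids)


def generate_compendium(cat: GeneCatalog, config: SynthConfig) -> Compendium:
    """Microarray-style log2 FC compendium with missingness.

    Dataset values are independent Normal(mu_g, sigma_g) draws, each
    masked missing with probability ``missing_rate``.
    """
    latents = compendium_latents(cat, config)
    rng = _rng(config.seed, "compendium", 1)
    shape = (len(cat), config.n_datasets)
    values = rng.normal(
        latents["mu"].to_numpy()[:, None],
        latents["sigma"].to_numpy()[:, None],
        size=shape,
    )
    if config.missing_rate > 0:
        mask = rng.random(size=shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    columns = [f"dataset{j + 1:02d}" for j in range(config.n_datasets)]
    return Compendium(pd.DataFrame(values, index=cat.gene_ids, columns=columns))


def generate_condition_expression(
    cat: GeneCatalog, config: SynthConfig
) -> pd.DataFrame:
    """Expression matrix over screen conditions (arbitrary units).

    The actin reference sits at a high stable level. A fixed fraction
    of BGC core genes is planted silent: their actin-relative level
    falls below 2% in at least 22 of the conditions. The remaining
    cores express at 5-20% of actin, mimicking robustly expressed
    synthetases; other genes span a broad log-uniform range.
    """
    rng = _rng(config.seed, "screen")
    n_cond = config.n_datasets
    actin_level = 1000.0
    cores = [g.gene_id for g in cat.core_genes()]
    n_silent = int(round(config.screen_silent_fraction * len(cores)))
    silent_cores = set(
        rng.choice(np.array(cores), size=n_silent, replace=False).tolist()
    ) if n_silent else set()
    min_silent = min(22, n_cond)
    levels = np.empty((len(cat), n_cond))
    noise = lambda size: np.exp(rng.normal(0.0, 0.1, size=size))  # noqa: E731
    for i, gene in enumerate(cat):
        gid = gene.gene_id
        if gene.is_actin:
            levels[i] = actin_level * noise(n_cond)
        elif gid in silent_cores:
            n_sil = int(rng.integers(min_silent, n_cond + 1))
            which = rng.choice(n_cond, size=n_sil, replace=False)
            row = actin_level * 0.05 * noise(n_cond)  # expressed elsewhere
            row[which] = actin_level * 0.002 * noise(n_sil)
            levels[i] = row
        elif gene.is_core:
            rel = rng.uniform(0.05, 0.20)
            levels[i] = actin_level * rel * noise(n_cond)
        else:
            rel = np.exp(rng.uniform(math.log(1e-3), math.log(1.0)))
            levels[i] = actin_level * rel * noise(n_cond)
    columns = [f"condition{j + 1:02d}" for j in range(n_cond)]
    return pd.DataFrame(levels, index=cat.gene_ids, columns=columns)


def generate_metabolite_table(
    config: SynthConfig,
    ref_strain: str = "reference",
    test_strain: str = "deletion",
) -> pd.DataFrame:
    """Replicate metabolite concentrations with LOD censoring.

    Replicates are lognormal around each true mean with coefficient of
    variation ``metabolite_cv`` (mean-preserving parameterisation).
    Extracellular draws below ``lod_nm`` are flagged below detection
    and carry no value; intracellular values (uM/g CDW) sit far above
    the nM detection limit and are never censored.
    """
    rng = _rng(config.seed, "metabolites")
    cv = config.metabolite_cv
    sigma = math.sqrt(math.log(1.0 + cv**2))
    rows = []
    for spec in config.metabolite_specs:
        for strain, true_mean in (
            (ref_strain, spec.ref_mean),
            (test_strain, spec.test_mean),
        ):
            mu = math.log(true_mean) - sigma**2 / 2.0
            draws = rng.lognormal(mu, sigma, size=config.n_metab_replicates)
            for r, value in enumerate(draws, start=1):
                censored = (
                    spec.compartment == "extracellular" and value < config.lod_nm
                )
                rows.append(
                    {
                        "analyte": spec.analyte,
                        "compartment": spec.compartment,
                        "strain": strain,
                        "replicate": r,
                        "value": math.nan if censored else float(value),
                        "below_detection": censored,
                    }
                )
    return pd.DataFrame(rows, columns=list(METABOLITE_COLUMNS))


def generate_qpcr_plate(
    true_fold_changes: Mapping[str, float],
    noise_sd_ct: float = 0.0,
    seed: int = 0,
    reference_gene: str = "actA",
    calibrator_sample: str = "reference",
    test_sample: str = "deletion",
    n_technical: int = 2,
) -> QpcrPlate:
    """Ct plate realising chosen fold changes against an actin reference.

    In the test sample each target's nominal Ct shifts by -log2(fold);
    target wells receive independent Normal(0, noise_sd_ct) noise, so
    each gene's ddCt is its -log2(fold) plus independent noise of
    standard deviation ``noise_sd_ct``. Reference-gene wells are noise
    free: shared reference noise would correlate every gene's estimate
    on the plate, while this generator models per-target error.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be nonnegative")
    rng = _rng(seed, "qpcr")
    actin_ct = 18.0
    target_ct = 24.0
    rows = []

    def wells(sample: str, gene: str, nominal: float, noisy: bool) -> None:
        for _ in range(n_technical):
            ct = nominal
            if noisy and noise_sd_ct:
                # sqrt(2)-scaled so the two-sample ddCt noise has the
                # requested standard deviation after replicate averaging
                ct += rng.normal(0.0, noise_sd_ct * math.sqrt(n_technical / 2.0))
            rows.append({"sample": sample, "gene": gene, "ct": ct})

    for sample in (calibrator_sample, test_sample):
        wells(sample, reference_gene, actin_ct, noisy=False)
    for gene, fold in true_fold_changes.items():
        wells(calibrator_sample, gene, target_ct, noisy=True)
        wells(test_sample, gene, target_ct - math.log2(fold), noisy=True)
    return QpcrPlate(
        pd.DataFrame(rows, columns=["sample", "gene", "ct"]),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )
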