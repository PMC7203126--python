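"""Readers and writers for catalogs, matrices, compendia and plates.

Canonical tabular dialect: tab-separated UTF-8 with a header row; a
blank cell (never ".") marks a missing value. Gene catalogs round-trip
through GFF3 (gene features only, 1-based inclusive coordinates) and
through TSV; every writer emits files its paired reader parses back to
an equal value.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

from .catalog import GeneCatalog, GeneRecord
from .crossplatform import Compendium
from .metabolomics import METABOLITE_COLUMNS, validate_metabolite_table
from .qpcr import QpcrPlate
from .synthdata import BgcSpec, MetaboliteSpec, SynthConfig

__all__ = [
    "read_gene_catalog",
    "write_gene_catalog",
    "read_matrix",
    "write_matrix",
    "read_compendium",
    "write_compendium",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_qpcr_plate",
    "write_qpcr_plate",
    "read_synth_config",
    "write_synth_config",
]

_GFF_SOURCE = "bgcprof"
_CATALOG_COLUMNS = [
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "bgc_id",
    "is_core",
    "categories",
    "is_actin",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# --------------------------------------------------------------------------
# gene catalog
# --------------------------------------------------------------------------

def write_gene_catalog(cat: GeneCatalog, path: str | Path, fmt: str = "gff3") -> None:
    path = Path(path)
    if fmt == "gff3":
        lines = ["##gff-version 3"]
        for g in cat:
            attrs = [f"ID={g.gene_id}"]
            if g.bgc_id is not None:
                attrs.append(f"bgc_id={g.bgc_id}")
            if g.is_core:
                attrs.append("core=1")
            if g.categories:
                attrs.append("categories=" + ",".join(sorted(g.categories)))
            if g.is_actin:
                attrs.append("actin=1")
            lines.append(
                "\t".join(
                    [
                        g.contig,
                        _GFF_SOURCE,
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "tsv":
        frame = cat.to_frame()[_CATALOG_COLUMNS].copy()
        frame["is_core"] = frame["is_core"].astype(int)
        frame["is_actin"] = frame["is_actin"].astype(int)
        frame.to_csv(path, sep="\t", index=False, na_rep="")
    else:
        raise ValueError(f"unknown catalog format {fmt!r}")


def read_gene_catalog(path: str | Path, fmt: str = "gff3") -> GeneCatalog:
    """Parse a catalog; contig order is order of first appearance."""
    path = Path(path)
    if fmt == "gff3":
        return _read_catalog_gff3(path)
    if fmt == "tsv":
        return _read_catalog_tsv(path)
    raise ValueError(f"unknown catalog format {fmt!r}")


def _read_catalog_gff3(path: Path) -> GeneCatalog:
    genes: list[GeneRecord] = []
    contig_order: list[str] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            feature = feature_from_line(raw)
        except Exception as exc:  # gffutils raises assorted exceptions
            raise ParseError(f"{path}:{lineno}: malformed GFF3 line ({exc})") from exc
        if feature.featuretype != "gene":
            continue
        try:
            gene_id = feature.attributes["ID"][0]
        except KeyError as exc:
            raise ParseError(f"{path}:{lineno}: gene feature without ID") from exc
        bgc = feature.attributes.get("bgc_id", [None])[0]
        categories = frozenset(
            c
            for value in feature.attributes.get("categories", [])
            for c in value.split(",")
            if c
        )
        try:
            record = GeneRecord(
                gene_id=gene_id,
                contig=feature.seqid,
                start=int(feature.start),
                end=int(feature.end),
                strand=feature.strand,
                bgc_id=bgc,
                is_core=feature.attributes.get("core", ["0"])[0] == "1",
                categories=categories,
                is_actin=feature.attributes.get("actin", ["0"])[0] == "1",
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(record)
        if feature.seqid not in contig_order:
            contig_order.append(feature.seqid)
    try:
        return GeneCatalog(genes, contig_order)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_catalog_tsv(path: Path) -> GeneCatalog:
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype={"gene_id": str, "contig": str}, keep_default_na=False
        )
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV catalog ({exc})") from exc
    missing = set(_CATALOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: catalog TSV missing columns {sorted(missing)}")
    genes = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            genes.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    contig=row.contig,
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    bgc_id=(str(row.bgc_id) or None),
                    is_core=bool(int(row.is_core)),
                    categories=frozenset(
                        c for c in str(row.categories).split(";") if c
                    ),
                    is_actin=bool(int(row.is_actin)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    contig_order = list(dict.fromkeys(frame["contig"]))
    try:
        return GeneCatalog(genes, contig_order)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# matrices and compendium
# --------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    # repr() emits the shortest digits that reproduce each double exactly,
    # so float cells survive the text round trip bit-for-bit
    matrix.to_csv(
        path,
        sep="\t",
        index_label="gene_id",
        na_rep="",
        float_format=lambda v: repr(float(v)),
    )


def read_matrix(path: str | Path, allow_missing: bool = False) -> pd.DataFrame:
    """Genes x samples matrix; first column gene ids, header sample ids."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse matrix ({exc})") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ParseError(f"{path}: matrix has no data")
    non_numeric = [
        c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])
    ]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in columns {non_numeric}")
    if not allow_missing and frame.isna().any().any():
        raise ParseError(f"{path}: missing cells are not allowed in this matrix")
    frame.index.name = None  # writers label it gene_id; keep matrices neutral
    return frame


def write_compendium(compendium: Compendium, path: str | Path) -> None:
    write_matrix(compendium.values, path)


def read_compendium(path: str | Path) -> Compendium:
    """Compendium TSV: one column per dataset, blank cells missing."""
    return Compendium(read_matrix(path, allow_missing=True))


# --------------------------------------------------------------------------
# metabolite tables and qPCR plates
# --------------------------------------------------------------------------

def write_metabolite_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_metabolite_table(table)
    out = table.loc[:, list(METABOLITE_COLUMNS)].copy()
    out["below_detection"] = out["below_detection"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_metabolite_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse metabolite table ({exc})") from exc
    missing = set(METABOLITE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: metabolite table missing columns {sorted(missing)}")
    frame["below_detection"] = frame["below_detection"].astype(bool)
    return validate_metabolite_table(frame)


def write_qpcr_plate(plate: QpcrPlate, path: str | Path) -> None:
    header = (
        f"# reference_gene={plate.reference_gene}\t"
        f"calibrator_sample={plate.calibrator_sample}\n"
    )
    body = plate.wells.to_csv(sep="\t", index=False)
    Path(path).write_text(header + body, encoding="utf-8")


def read_qpcr_plate(path: str | Path) -> QpcrPlate:
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text or not text[0].startswith("#"):
        raise ParseError(f"{path}: missing plate metadata header line")
    meta = dict(
        item.split("=", 1) for item in text[0].lstrip("# ").split("\t") if "=" in item
    )
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse plate ({exc})") from exc
    try:
        return QpcrPlate(
            frame,
            reference_gene=meta["reference_gene"],
            calibrator_sample=meta["calibrator_sample"],
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def write_synth_config(config: SynthConfig, path: str | Path) -> None:
    doc: dict[str, Any] = dataclasses.asdict(config)
    doc["gene_length_range"] = list(config.gene_length_range)
    doc["baseline_mean_range"] = list(config.baseline_mean_range)
    doc["compendium_sigma_range"] = list(config.compendium_sigma_range)
    doc["bgc_specs"] = [dataclasses.asdict(s) for s in config.bgc_specs]
    doc["metabolite_specs"] = [dataclasses.asdict(s) for s in config.metabolite_specs]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_synth_config(path: str | Path) -> SynthConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    doc = dict(doc)
    for key in ("gene_length_range", "baseline_mean_range", "compendium_sigma_range"):
        if key in doc:
            doc[key] = tuple(doc[key])
    if "bgc_specs" in doc:
        doc["bgc_specs"] = tuple(BgcSpec(**s) for s in doc["bgc_specs"])
    if "metabolite_specs" in doc:
        doc["metabolite_specs"] = tuple(
            MetaboliteSpec(**s) for s in doc["metabolite_specs"]
        )
    try:
        return SynthConfig(**doc)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid config ({exc})") from exc
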