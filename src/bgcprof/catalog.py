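"""Gene catalog: ordered genes on contigs with BGC and category labels.

The catalog is the genomic backbone of every stage: it fixes the contig
order and within-contig gene order used for cluster detection, carries
BGC membership (with one flagged core synthase/synthetase per cluster),
functional category labels for enrichment, and the gamma-actin reference
gene used for relative expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive genomic coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    bgc_id: str | None = None
    is_core: bool = False
    categories: frozenset[str] = field(default_factory=frozenset)
    is_actin: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates [{self.start}, {self.end}]"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.is_core and self.bgc_id is None:
            raise ValueError(f"gene {self.gene_id}: core flag requires a BGC label")
        object.__setattr__(self, "categories", frozenset(self.categories))

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


class GeneCatalog:
    """Ordered collection of :class:`GeneRecord` across contigs.

    Genes are stored sorted by (contig rank, start); contig rank follows
    ``contig_order`` (first appearance order when not given). Gene
    identifiers must be unique and at most one gene may carry the actin
    flag.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        contig_order: Sequence[str] | None = None,
    ) -> None:
        genes = list(genes)
        if contig_order is None:
            contig_order = list(dict.fromkeys(g.contig for g in genes))
        else:
            contig_order = list(contig_order)
            missing = {g.contig for g in genes} - set(contig_order)
            if missing:
                raise ValueError(f"genes on contigs absent from contig_order: {missing}")
        rank = {c: i for i, c in enumerate(contig_order)}
        genes.sort(key=lambda g: (rank[g.contig], g.start))
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        actin = [g.gene_id for g in genes if g.is_actin]
        if len(actin) > 1:
            raise ValueError(f"more than one actin reference gene: {actin}")
        # overlapping genes on one contig would make run detection ambiguous
        prev: GeneRecord | None = None
        for g in genes:
            if prev is not None and prev.contig == g.contig and g.start <= prev.end:
                raise ValueError(
                    f"overlapping genes {prev.gene_id} and {g.gene_id} on {g.contig}"
                )
            prev = g
        self._genes = genes
        self._contig_order = contig_order
        self._by_id = {g.gene_id: g for g in genes}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalog):
            return NotImplemented
        return self._genes == other._genes and self._contig_order == other._contig_order

    # -- accessors ----------------------------------------------------------
    @property
    def genes(self) -> list[GeneRecord]:
        return list(self._genes)

    @property
    def contig_order(self) -> list[str]:
        return list(self._contig_order)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]

    @property
    def actin_gene(self) -> GeneRecord | None:
        for g in self._genes:
            if g.is_actin:
                return g
        return None

    def core_genes(self) -> list[GeneRecord]:
        return [g for g in self._genes if g.is_core]

    def bgc_ids(self) -> list[str]:
        return list(dict.fromkeys(g.bgc_id for g in self._genes if g.bgc_id))

    def bgc_members(self, bgc_id: str) -> list[GeneRecord]:
        return [g for g in self._genes if g.bgc_id == bgc_id]

    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            [g.length_bp for g in self._genes], index=self.gene_ids, name="length_bp"
        )

    def categories(self) -> dict[str, frozenset[str]]:
        return {g.gene_id: g.categories for g in self._genes}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per gene, in genome order."""
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self._genes],
                "contig": [g.contig for g in self._genes],
                "start": [g.start for g in self._genes],
                "end": [g.end for g in self._genes],
                "strand": [g.strand for g in self._genes],
                "length_bp": [g.length_bp for g in self._genes],
                "bgc_id": [g.bgc_id for g in self._genes],
                "is_core": [g.is_core for g in self._genes],
                "categories": [";".join(sorted(g.categories)) for g in self._genes],
                "is_actin": [g.is_actin for g in self._genes],
            }
        )
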