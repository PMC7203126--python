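"""Relative quantification from qPCR Ct tables by the 2^-ddCt method.

Technical replicates are averaged in Ct space. With a reference gene
(gamma-actin) for normalisation and a calibrator sample:

    dCt(sample)  = mean Ct(target) - mean Ct(reference)
    ddCt         = dCt(test) - dCt(calibrator)
    fold change  = 2^-ddCt

Amplification efficiency is assumed to be 2.0 per cycle. The same
arithmetic on genomic DNA with a single-copy reference gene and a
known single-copy calibrator strain yields integration copy numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "QpcrPlate",
    "ddct_relative_expression",
    "actin_relative_level",
    "copy_number_from_gdna",
]


@dataclass(frozen=True)
class QpcrPlate:
    """Ct measurements with one row per technical replicate.

    ``wells`` columns: ``sample``, ``gene``, ``ct``. The reference gene
    must be measured in every sample.
    """

    wells: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        missing = {"sample", "gene", "ct"} - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if self.wells["ct"].isna().any():
            raise ValueError("Ct values must not be missing")
        for sample in self.wells["sample"].unique():
            sub = self.wells.loc[self.wells["sample"] == sample, "gene"]
            if self.reference_gene not in set(sub):
                raise ValueError(
                    f"reference gene {self.reference_gene} absent from sample {sample}"
                )
        if self.calibrator_sample not in set(self.wells["sample"]):
            raise ValueError(
                f"calibrator sample {self.calibrator_sample} absent from plate"
            )

    def mean_ct(self, sample: str, gene: str) -> float:
        """Mean Ct over technical replicates of one well group."""
        mask = (self.wells["sample"] == sample) & (self.wells["gene"] == gene)
        cts = self.wells.loc[mask, "ct"]
        if len(cts) == 0:
            raise ValueError(f"no Ct for gene {gene} in sample {sample}")
        return float(cts.mean())

    def delta_ct(self, sample: str, gene: str) -> float:
        return self.mean_ct(sample, gene) - self.mean_ct(sample, self.reference_gene)


def ddct_relative_expression(
    plate: QpcrPlate, target_gene: str, test_sample: str
) -> float:
    """Fold change of the target in the test sample vs the calibrator."""
    ddct = plate.delta_ct(test_sample, target_gene) - plate.delta_ct(
        plate.calibrator_sample, target_gene
    )
    return 2.0**-ddct


def actin_relative_level(plate: QpcrPlate, target_gene: str, sample: str) -> float:
    """Expression as a fraction of the reference (actin) level in one sample.

    2^-(mean Ct(target) - mean Ct(reference)); a value below 0.05 is the
    conventional "low expression" call.
    """
    return 2.0 ** -(plate.mean_ct(sample, target_gene) - plate.mean_ct(sample, plate.reference_gene))


def copy_number_from_gdna(
    plate: QpcrPlate,
    construct_gene: str,
    single_copy_gene: str,
    test_sample: str,
    single_copy_calibrator: str,
) -> tuple[float, int]:
    """Integrated-construct copy number from a genomic-DNA plate.

    Relative quantity is 2^-ddCt with the single-copy gene as reference
    and a known single-copy strain as calibrator. Copies are rounded
    half away from zero.
    """

    def dct(sample: str) -> float:
        return plate.mean_ct(sample, construct_gene) - plate.mean_ct(
            sample, single_copy_gene
        )

    ddct = dct(test_sample) - dct(single_copy_calibrator)
    quantity = 2.0**-ddct
    copies = int(math.floor(quantity + 0.5))
    return quantity, copies
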