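"""Expression compendium container and its TSV interchange format.

The compendium holds a genes x samples TPM matrix plus a sample sheet
(group and clone labels per sample). TPM (transcripts per million) is a
within-sample-normalized expression unit, so values are non-negative and
finite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionCompendium:
    """Genes x samples TPM matrix with per-sample annotations.

    Attributes
    ----------
    tpm:
        DataFrame indexed by gene id, one column per sample, values TPM.
    sample_sheet:
        DataFrame with columns ``sample_id``, ``group``, ``clone``; one row
        per sample, in the same order as the matrix columns.
    """

    tpm: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.tpm.index
        samples = self.tpm.columns
        if genes.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if samples.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        vals = self.tpm.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("TPM matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("TPM matrix contains negative values")
        required = {"sample_id", "group"}
        if not required <= set(self.sample_sheet.columns):
            raise ValueError("sample sheet needs columns sample_id and group")
        if "clone" not in self.sample_sheet.columns:
            self.sample_sheet = self.sample_sheet.assign(clone="")
        sheet_ids = list(self.sample_sheet["sample_id"])
        if sheet_ids != list(samples):
            raise ValueError("sample sheet ids do not match matrix columns")
        if self.sample_sheet["group"].isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.sample_sheet["group"] == group
        return list(self.sample_sheet.loc[mask, "sample_id"])

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_sheet["group"]))

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        """Write matrix TSV (first column ``gene_id``) and sample sheet TSV."""
        out = self.tpm.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.6g")
        self.sample_sheet.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path: str | Path, samples_path: str | Path) -> "ExpressionCompendium":
        tpm = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "group": str, "clone": str})
        return cls(tpm=tpm, sample_sheet=sheet)
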