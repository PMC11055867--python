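"""Gene-by-sample expression container used by every stage.

An :class:`ExpressionMatrix` couples a genes x samples table with the sample
group labels (the study design has three groups: polyp tissue, paired
turbinate tissue and control turbinate).  On disk it is a plain TSV with the
gene identifier in the first column and one column per sample, plus a
two-column sample metadata TSV (sample id, group label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    groups
        Series mapping sample id -> group name; must cover every sample.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InputError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample identifiers in expression matrix")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise InputError(f"group labels missing for samples: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise InputError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise InputError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.groups)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, expression_path, metadata_path=None) -> None:
        """Write the expression TSV (and optionally the metadata TSV)."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(expression_path, sep="\t", lineterminator="\n")
        if metadata_path is not None:
            meta = pd.DataFrame(
                {"sample_id": self.sample_ids, "group": self.groups.values}
            )
            meta.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionMatrix":
        expression_path, metadata_path = Path(expression_path), Path(metadata_path)
        for p in (expression_path, metadata_path):
            if not p.exists():
                raise InputError(f"input file not found: {p}")
        try:
            values = pd.read_csv(expression_path, sep="\t", index_col=0)
        except Exception as exc:  # malformed TSV
            raise InputError(f"could not parse expression TSV {expression_path}: {exc}")
        try:
            meta = pd.read_csv(metadata_path, sep="\t")
        except Exception as exc:
            raise InputError(f"could not parse metadata TSV {metadata_path}: {exc}")
        if not {"sample_id", "group"} <= set(meta.columns):
            raise InputError(
                "metadata TSV must have columns 'sample_id' and 'group', "
                f"got {list(meta.columns)}"
            )
        groups = pd.Series(
            meta["group"].values, index=meta["sample_id"].astype(str), name="group"
        )
        values.columns = values.columns.astype(str)
        return cls(values, groups)
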