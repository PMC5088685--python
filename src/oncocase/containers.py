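"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class ExpressionMatrix:
    """A gene x sample abundance table (FPKM) with sample and gene metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM values, genes in rows (index = gene
        ids), samples in columns (columns = sample ids).
    sample_labels
        Optional tissue label per sample (index aligned with ``values``
        columns).
    gene_roles
        Role per gene, ``"housekeeping"`` or ``"other"`` (index aligned with
        ``values`` index).
    """

    values: pd.DataFrame
    sample_labels: pd.Series | None = None
    gene_roles: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        if self.gene_roles.empty:
            self.gene_roles = pd.Series("other", index=self.values.index)
        if not self.gene_roles.index.equals(self.values.index):
            raise ValueError("gene_roles index must match values index")
        if self.sample_labels is not None and not self.sample_labels.index.equals(
            pd.Index(self.values.columns)
        ):
            raise ValueError("sample_labels index must match values columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def housekeeping_ids(self) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == "housekeeping"])

    # --- TSV round trip -------------------------------------------------
    def to_tsv(self, values_path: str | Path, labels_path: str | Path | None = None,
               housekeeping_path: str | Path | None = None) -> None:
        """Write the matrix (and optional sidecars) as tab-separated text."""
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        if labels_path is not None and self.sample_labels is not None:
            self.sample_labels.rename("tissue").to_csv(
                labels_path, sep="\t", index_label="sample"
            )
        if housekeeping_path is not None:
            Path(housekeeping_path).write_text(
                "".join(g + "\n" for g in self.housekeeping_ids)
            )

    @classmethod
    def from_tsv(cls, values_path: str | Path, labels_path: str | Path | None = None,
                 housekeeping_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene")
        labels = None
        if labels_path is not None:
            labels = pd.read_csv(labels_path, sep="\t", index_col="sample")["tissue"]
            labels = labels.reindex(values.columns)
        roles = pd.Series("other", index=values.index)
        if housekeeping_path is not None:
            hk = [ln.strip() for ln in Path(housekeeping_path).read_text().splitlines() if ln.strip()]
            roles.loc[roles.index.intersection(hk)] = "housekeeping"
        return cls(values=values, sample_labels=labels, gene_roles=roles)
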