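"""Expression and CRISPR-dependency tables (thin pandas wrappers)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DEPENDENCY_COLUMNS = ["gene", "lineage", "gene_effect", "t_statistic", "adj_p"]


@dataclass
class ExpressionTable:
    """Genes x samples log2 expression with optional sample group labels."""

    values: pd.DataFrame  # index: gene symbols, columns: sample ids
    groups: dict[str, str] = field(default_factory=dict)  # sample -> case/control/other

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene labels: {dupes[:5]}")
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]


def read_expression(path: str | Path,
                    groups: dict[str, str] | None = None) -> ExpressionTable:
    """Read a TSV with a leading gene column and one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionTable(df, dict(groups or {}))


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")


def read_dependency(path: str | Path) -> pd.DataFrame:
    """Read a dependency CSV (gene, lineage, gene_effect, t_statistic, adj_p).

    ``gene_effect`` is a Chronos-style fitness score (more negative =
    stronger dependency); ``t_statistic`` compares the lineage against all
    other models; ``adj_p`` must lie in [0, 1].
    """
    df = pd.read_csv(path)
    missing = [c for c in DEPENDENCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing dependency columns {missing}")
    bad = df[(df["adj_p"] < 0) | (df["adj_p"] > 1)]
    if len(bad):
        raise ValueError(
            f"{path}: adj_p outside [0, 1] for genes {bad['gene'].tolist()[:5]}"
        )
    return df
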