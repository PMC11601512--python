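"""Sparse count-table I/O: MatrixMarket + row/column TSVs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["write_counts_mtx", "read_counts_mtx"]


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write a cell-by-feature table as ``<prefix>.mtx`` with
    ``<prefix>.cells.tsv`` / ``<prefix>.features.tsv`` annotations."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="cell_id").to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False
    )
    pd.Series(counts.columns, name="feature").to_csv(
        str(prefix) + ".features.tsv", sep="\t", index=False
    )


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")["cell_id"]
    feats = pd.read_csv(prefix + ".features.tsv", sep="\t")["feature"]
    return pd.DataFrame(mat, index=cells, columns=feats)
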