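"""Per-cell perturbation calling and cell/gene filtering.

Two calling routes mirror the two readout modalities:

* imaging barcodes — a guide is called when its decoded barcode count is
  strictly greater than the threshold (default 3 molecules per cell);
* sequencing sgRNA probes — a guide is called when its spike-in probe UMI
  count reaches its threshold (inclusive), the threshold being global or
  per-guide.

Only cells with exactly one called guide (status ``single``) enter
perturbation analyses. Cell/gene filtering removes cells with fewer than
25 or more than 1500 molecules (boundaries kept) and then genes expressed
in fewer than 3 remaining cells, in that order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "call_imaging_barcodes",
    "call_sequencing_sgrnas",
    "default_sequencing_thresholds",
    "filter_cells_genes",
]


def _status(n_called: int) -> str:
    return {0: "none", 1: "single"}.get(n_called, "multiple")


def _calls_frame(counts: pd.DataFrame, called_mask: np.ndarray) -> pd.DataFrame:
    guides = np.array(counts.columns)
    rows = []
    for i, cell_id in enumerate(counts.index):
        called = list(guides[called_mask[i]])
        rows.append(
            {
                "cell_id": cell_id,
                "status": _status(len(called)),
                "guides": tuple(called),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def call_imaging_barcodes(
    barcode_counts: pd.DataFrame, threshold: int = 3
) -> pd.DataFrame:
    """Call guides from decoded barcode molecule counts per cell.

    A guide is called iff its count is strictly greater than ``threshold``
    (the "> 3 molecules per cell" rule). Returns a frame indexed by cell
    with ``status`` in {none, single, multiple} and the called guide tuple.
    """
    counts = barcode_counts.fillna(0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("barcode counts must be nonnegative")
    return _calls_frame(counts, counts.to_numpy() > threshold)


def default_sequencing_thresholds(
    umis: pd.DataFrame, floor: int = 5, ambient_quantile: float = 0.95
) -> pd.Series:
    """Global sgRNA UMI threshold from the ambient count distribution.

    The ambient pool is every guide-probe count that is not its cell's
    argmax (those are overwhelmingly background); the threshold is
    ``max(floor, ceil(q95 of ambient) + 1)`` applied to every guide.
    """
    arr = umis.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        ambient = np.array([0.0])
    else:
        argmax = arr.argmax(axis=1)
        mask = np.ones_like(arr, dtype=bool)
        mask[np.arange(len(arr)), argmax] = False
        ambient = arr[mask]
    thr = max(float(floor), float(np.ceil(np.quantile(ambient, ambient_quantile)) + 1))
    return pd.Series(thr, index=umis.columns)


def call_sequencing_sgrnas(
    umis: pd.DataFrame, thresholds: pd.Series | float | None = None
) -> pd.DataFrame:
    """Call guides from sgRNA spike-in probe UMIs.

    A guide is called iff its UMI count is at or above its threshold
    (inclusive). ``thresholds`` may be a scalar, a per-guide Series, or
    None (derived via :func:`default_sequencing_thresholds`). Only cells
    with exactly one called guide should be retained downstream.
    """
    counts = umis.fillna(0)
    if thresholds is None:
        thresholds = default_sequencing_thresholds(counts)
    if np.isscalar(thresholds):
        thresholds = pd.Series(float(thresholds), index=counts.columns)
    thresholds = thresholds.reindex(counts.columns)
    if thresholds.isna().any() or (thresholds < 1).any():
        raise ValueError("per-guide thresholds must be >= 1 for every guide")
    called = counts.to_numpy() >= thresholds.to_numpy()[None, :]
    return _calls_frame(counts, called)


def filter_cells_genes(
    counts: pd.DataFrame,
    min_molecules: int = 25,
    max_molecules: int = 1500,
    min_cells_per_gene: int = 3,
) -> pd.DataFrame:
    """Standard cell/gene filter, cells first then genes.

    Cells with totals below ``min_molecules`` or above ``max_molecules``
    are removed (the boundaries themselves are kept); genes with nonzero
    counts in fewer than ``min_cells_per_gene`` remaining cells are then
    removed. An empty result is allowed.
    """
    totals = counts.sum(axis=1)
    kept = counts.loc[(totals >= min_molecules) & (totals <= max_molecules)]
    expressed_in = (kept > 0).sum(axis=0)
    return kept.loc[:, expressed_in >= min_cells_per_gene]
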