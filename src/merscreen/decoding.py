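"""Spot detection, codeword decoding, misidentification filtering, and
molecule-to-cell assignment.

Amplified FISH produces bright, well-separated amplicons, so decoding here
is spot-based: local maxima of the across-bit maximum projection become
spots, each spot's per-bit intensities are normalized (per-bit 90th
percentile) and binarized, and the bit vector is decoded against the
codebook with radius-1 error correction.

Misidentified molecules are filtered with a classifier trained to separate
blank-assigned from coding-assigned molecules on quality features (on/off
intensities, Hamming distance, area), applied with cross-fitting so no
molecule is scored by a model trained on it. The retained set is chosen at
the smallest score cutoff whose blank-based misidentification estimate

    m(c) = (retained blanks / #blank codewords)
           / (retained coding / #coding codewords)

stays at or below the target rate (default 5%); blank-assigned molecules
are never exported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .codebook import Codebook

__all__ = [
    "detect_spots",
    "decode_spots",
    "MisidFilter",
    "fit_misid_filter",
    "apply_adaptive_threshold",
    "assign_to_cells",
    "QUALITY_FEATURES",
    "DegenerateInputError",
]

QUALITY_FEATURES = ["mean_on", "mean_off", "on_off_ratio", "distance", "area"]


class DegenerateInputError(ValueError):
    pass


def detect_spots(
    images: np.ndarray,
    min_separation: int = 3,
    threshold: float = 0.3,
    radius: int = 2,
) -> tuple:
    """Detect amplicon spots on the across-bit maximum projection.

    Returns ``(xy_px, intensities, areas)``: peak coordinates (x, y) in
    pixels, per-bit intensity (max within ``radius`` of the peak in each
    plane), and the pixel area of the above-threshold region at the peak.
    """
    if images.ndim != 3:
        raise ValueError("images must be a (n_bits, H, W) stack")
    proj = images.max(axis=0)
    peaks = peak_local_max(
        proj, min_distance=min_separation, threshold_abs=threshold, exclude_border=False
    )
    if len(peaks) == 0:
        return np.zeros((0, 2)), np.zeros((0, images.shape[0])), np.zeros(0, dtype=int)

    footprint = _disk_footprint(radius)
    maxed = np.stack(
        [ndimage.maximum_filter(plane, footprint=footprint) for plane in images]
    )
    intensities = maxed[:, peaks[:, 0], peaks[:, 1]].T

    lab, _ = ndimage.label(proj > threshold)
    sizes = np.bincount(lab.ravel())
    areas = sizes[lab[peaks[:, 0], peaks[:, 1]]]

    xy = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return xy, intensities.astype(float), areas.astype(int)


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def decode_spots(
    intensities: np.ndarray,
    codebook: Codebook,
    xy: np.ndarray | None = None,
    areas: np.ndarray | None = None,
    norm_percentile: float = 90.0,
    binarize_threshold: float = 0.5,
    max_correction: int = 1,
) -> pd.DataFrame:
    """Decode per-spot intensity vectors against the codebook.

    Intensities are scaled by each bit's ``norm_percentile`` over all spots
    and binarized at ``binarize_threshold``; the bit vector is decoded with
    the radius-``max_correction`` rule (ties and out-of-radius vectors are
    no-calls). Quality features are populated for the downstream filter.
    """
    intensities = np.asarray(intensities, dtype=float)
    n_spots, n_bits = intensities.shape
    if n_bits != codebook.n_bits:
        raise ValueError("intensity matrix width must equal codebook n_bits")

    norm = np.percentile(intensities, norm_percentile, axis=0)
    norm = np.where(norm <= 0, 1.0, norm)
    scaled = intensities / norm
    bits = (scaled > binarize_threshold).astype(np.int32)

    mat = codebook.bit_matrix.astype(np.int32)
    w = mat.sum(axis=1)
    overlap = bits @ mat.T
    dist = bits.sum(axis=1)[:, None] + w[None, :] - 2 * overlap  # Hamming

    dmin = dist.min(axis=1)
    n_at_min = (dist == dmin[:, None]).sum(axis=1)
    best = dist.argmin(axis=1)
    callable_ = (dmin <= max_correction) & (n_at_min == 1)

    idx_arr = np.array([cw.index for cw in codebook.codewords])
    outcome = np.where(callable_, "target", "no_call").astype(object)
    cw_index = np.where(callable_, idx_arr[best], -1)
    blank_set = set(codebook.blank_indices)
    for i in np.flatnonzero(callable_):
        if int(cw_index[i]) in blank_set:
            outcome[i] = "blank"

    on_mask = mat[best].astype(bool)
    mean_on = np.where(
        on_mask, scaled, np.nan
    )
    mean_on = np.nanmean(np.where(on_mask, scaled, np.nan), axis=1)
    mean_off = np.nanmean(np.where(~on_mask, scaled, np.nan), axis=1)
    ratio = mean_on / np.maximum(mean_off, 1e-6)

    df = pd.DataFrame(
        {
            "codeword_index": cw_index,
            "outcome": outcome,
            "distance": dmin,
            "mean_on": mean_on,
            "mean_off": mean_off,
            "on_off_ratio": ratio,
            "area": areas if areas is not None else np.full(n_spots, 9),
        }
    )
    df["target"] = [
        codebook.name_of(int(i)) if o == "target" else None
        for i, o in zip(df["codeword_index"], df["outcome"])
    ]
    if xy is not None:
        df.insert(0, "x", np.asarray(xy)[:, 0])
        df.insert(1, "y", np.asarray(xy)[:, 1])
    return df


# --------------------------------------------------------------------------
# misidentification filter


@dataclass
class MisidFilter:
    """Cross-fitted boosted-tree classifier separating blank- from
    coding-assigned molecules on the quality features."""

    models: list
    features: list
    seed: int

    def score(self, molecules: pd.DataFrame) -> np.ndarray:
        """Mean P(coding) over the fold models (for molecules outside the
        training set; training molecules should use their out-of-fold
        scores from :func:`fit_misid_filter`)."""
        X = molecules[self.features].to_numpy(dtype=float)
        return np.mean([m.predict_proba(X)[:, 1] for m in self.models], axis=0)


def fit_misid_filter(
    molecules: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 5,
    n_estimators: int = 100,
    max_depth: int = 3,
) -> tuple:
    """Train the blank-vs-coding classifier with cross-fitting.

    Uses only called molecules (outcome target or blank). Labels: coding
    assignment = 1, blank assignment = 0. Returns ``(filter, scores)``
    where ``scores`` is a Series of out-of-fold P(coding) aligned to the
    called molecules' index, so every score comes from a model not trained
    on that molecule.
    """
    called = molecules[molecules["outcome"].isin(["target", "blank"])]
    y = (called["outcome"] == "target").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError(
            "need at least one blank-assigned and one coding-assigned molecule"
        )
    X = called[QUALITY_FEATURES].to_numpy(dtype=float)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    params = dict(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=0.2,
        n_jobs=1,
        random_state=seed,
        base_score=0.5,
        tree_method="hist",
        verbosity=0,
    )
    scores = np.zeros(len(y))
    models = []
    if n_folds < 2:
        # too few minority examples to cross-fit; single model, in-sample scores
        model = XGBClassifier(**params)
        model.fit(X, y)
        scores = model.predict_proba(X)[:, 1]
        models = [model]
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            model = XGBClassifier(**params)
            model.fit(X[train], y[train])
            scores[test] = model.predict_proba(X[test])[:, 1]
            models.append(model)
    filt = MisidFilter(models=models, features=QUALITY_FEATURES, seed=seed)
    return filt, pd.Series(scores, index=called.index, name="classifier_score")


def misid_estimate(
    retained_blanks: int, retained_coding: int, n_blank_codewords: int, n_coding_codewords: int
) -> float:
    """Blank-per-codeword misidentification estimate."""
    if retained_coding == 0:
        return np.inf if retained_blanks > 0 else 0.0
    return (retained_blanks / n_blank_codewords) / (
        retained_coding / n_coding_codewords
    )


def apply_adaptive_threshold(
    molecules: pd.DataFrame,
    scores: pd.Series,
    n_blank_codewords: int,
    n_coding_codewords: int,
    target_rate: float = 0.05,
) -> tuple:
    """Retain coding molecules at the most permissive cutoff meeting the
    target misidentification rate.

    Sweeps score cutoffs (descending retention), computes the blank-based
    estimate m(c) at each, and picks the smallest cutoff with
    ``m <= target_rate``. Returns ``(retained, achieved_m, cutoff)``;
    ``retained`` contains coding-assigned molecules only — blanks are
    always dropped from the export. If no cutoff achieves the target the
    retained set is empty (with a warning).
    """
    called = molecules[molecules["outcome"].isin(["target", "blank"])].copy()
    called["classifier_score"] = scores.loc[called.index]
    if n_blank_codewords < 1 or n_coding_codewords < 1:
        raise ValueError("codeword counts must be positive")

    order = called["classifier_score"].sort_values(ascending=False)
    is_blank = (called.loc[order.index, "outcome"] == "blank").to_numpy()
    cum_blank = np.cumsum(is_blank)
    cum_coding = np.cumsum(~is_blank)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (cum_blank / n_blank_codewords) / np.where(
            cum_coding > 0, cum_coding / n_coding_codewords, np.nan
        )
    m = np.where(np.isnan(m), np.where(cum_blank > 0, np.inf, 0.0), m)

    # candidate cutoffs sit at distinct-score boundaries so that the
    # retained set is exactly {score >= cutoff} even under ties
    vals = order.to_numpy()
    boundary = np.append(vals[:-1] > vals[1:], True)
    ok = np.flatnonzero((m <= target_rate) & boundary)
    if len(ok) == 0:
        warnings.warn(
            f"no score cutoff achieves misidentification <= {target_rate}; "
            "retaining no molecules"
        )
        empty = called.iloc[0:0]
        achieved = float(m[-1]) if len(m) else 0.0
        return empty, achieved, float("inf")

    k = int(ok[-1])  # most inclusive cutoff meeting the target
    cutoff = float(order.iloc[k])
    keep_idx = order.index[: k + 1]
    retained = called.loc[keep_idx]
    retained = retained[retained["outcome"] == "target"]
    achieved = float(m[k])
    return retained, achieved, cutoff


# --------------------------------------------------------------------------
# cell assignment


def assign_to_cells(
    molecules: pd.DataFrame,
    masks: np.ndarray,
    pixel_size_um: float = 1.0,
    target_column: str = "target",
) -> tuple:
    """Assign molecules to segmentation labels and build count tables.

    The molecule's pixel label becomes its ``cell_id`` (0 = unassigned).
    Returns ``(molecules_with_cell, counts)`` where ``counts`` is a
    cell-by-target integer table over assigned molecules.
    """
    mol = molecules.copy()
    col = np.clip(
        (mol["x"].to_numpy() / pixel_size_um).astype(int), 0, masks.shape[1] - 1
    )
    row = np.clip(
        (mol["y"].to_numpy() / pixel_size_um).astype(int), 0, masks.shape[0] - 1
    )
    mol["cell_id"] = masks[row, col].astype(int)
    assigned = mol[mol["cell_id"] > 0]
    counts = (
        assigned.groupby(["cell_id", target_column]).size().unstack(fill_value=0)
    )
    counts.columns.name = None
    return mol, counts
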