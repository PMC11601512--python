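"""Statistical analyses for pooled-perturbation screens.

Implements the screen's analysis stack: per-cell tp10k + log1p
normalization, covariate regression, z-scoring against negative-control
cells within batch, energy-distance permutation testing of whole-
transcriptome shifts on PC scores, Mann-Whitney differential expression
with Benjamini-Hochberg control, pseudobulk profiles and correlations over
highly expressed genes, gene-set and zonation scores, and per-channel
intensity effects with Benjamini-Yekutieli control.

The energy distance between cell populations X and Y is

    E(X, Y) = 2 E d(X, Y) - E d(X, X') - E d(Y, Y')

with d squared Euclidean on the first ``n_pcs`` principal components by
default (configurable to Euclidean); significance comes from permuting
group-versus-control labels, with Holm-Sidak family-wise correction across
guides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PERIPORTAL_MARKERS",
    "PERICENTRAL_MARKERS",
    "ZonationMarkers",
    "StatsConfig",
    "NormalizedLayers",
    "normalize_and_zscore",
    "energy_distance",
    "energy_distance_test",
    "differential_expression",
    "pseudobulk_profiles",
    "gene_set_score",
    "zonation_score",
    "guide_zonation_scores",
    "intensity_effects",
]

#: Literature-curated hepatocyte zonation markers. Periportal expression
#: contributes positively to the zonation score, pericentral negatively.
PERIPORTAL_MARKERS = (
    "Cyp2f2", "Hal", "Hsd17b13", "Sds", "Ctsc", "Aldh1b1", "Pck1",
)
PERICENTRAL_MARKERS = (
    "Cyp4a14", "Cyp2d9", "Gstm3", "Cyp4a10", "Mup17", "Slc1a2", "Slc22a1",
    "Cyp1a2", "Aldh1a1", "Cyp2a5", "Gulo", "Cyp2c37", "Lect2", "Cyp2e1",
    "Oat", "Glul",
)


@dataclass(frozen=True)
class ZonationMarkers:
    periportal: tuple = PERIPORTAL_MARKERS
    pericentral: tuple = PERICENTRAL_MARKERS

    def __post_init__(self):
        if set(self.periportal) & set(self.pericentral):
            raise ValueError("periportal and pericentral marker sets must be disjoint")


@dataclass
class StatsConfig:
    """Knobs shared across the analyses.

    Multiple-testing conventions: Holm-Sidak (family-wise) for the
    transcriptional energy-distance tests, Benjamini-Hochberg for
    differential expression, Benjamini-Yekutieli for intensity and
    gene-set/zonation score tests.
    """

    n_pcs: int = 20
    n_permutations: int = 1000
    alpha: float = 0.05
    metric: str = "sqeuclidean"  # or "euclidean"
    top_n_pseudobulk: int = 250
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.metric not in ("sqeuclidean", "euclidean"):
            raise ValueError("metric must be 'sqeuclidean' or 'euclidean'")


@dataclass
class NormalizedLayers:
    tp10k_log: pd.DataFrame
    residual: pd.DataFrame | None
    z: pd.DataFrame
    excluded_genes: list


def tp10k_log(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell to a total of 10,000 then log1p."""
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(zero.index[:5])}")
    return np.log1p(counts.div(totals, axis=0) * 10_000.0)


def _regress_out(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    X = np.column_stack([np.ones(len(values)), covariates.to_numpy(dtype=float)])
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ beta, index=values.index, columns=values.columns)


def normalize_and_zscore(
    counts: pd.DataFrame,
    control_mask: pd.Series | np.ndarray,
    batch: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
) -> NormalizedLayers:
    """tp10k-log layer, optional covariate residuals, and control z-scores.

    The z layer is (value - control mean) / control sd per gene, computed
    within each batch and concatenated; genes with zero control variance in
    any batch are excluded from the z layer (and listed).
    """
    control_mask = pd.Series(np.asarray(control_mask, dtype=bool), index=counts.index)
    log_layer = tp10k_log(counts)
    residual = _regress_out(log_layer, covariates) if covariates is not None else None
    base = residual if residual is not None else log_layer

    if batch is None:
        batch = pd.Series("all", index=counts.index)
    batch = pd.Series(batch, index=counts.index)

    z_parts = []
    excluded: set = set()
    for b in batch.unique():
        sel = batch == b
        ctrl = base[sel & control_mask]
        if len(ctrl) == 0:
            raise ValueError(f"no control cells in batch {b!r}")
        mean, sd = ctrl.mean(axis=0), ctrl.std(axis=0, ddof=0)
        excluded |= set(sd.index[sd == 0])
        z_parts.append((base[sel] - mean) / sd.replace(0, np.nan))
    z = pd.concat(z_parts).loc[counts.index]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance gene(s) in controls from z layer"
        )
        z = z.drop(columns=sorted(excluded))
    return NormalizedLayers(log_layer, residual, z, sorted(excluded))


# --------------------------------------------------------------------------
# energy distance


def _pairwise(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, Y, metric=metric)


def energy_distance(X: np.ndarray, Y: np.ndarray, metric: str = "sqeuclidean") -> float:
    """E(X, Y) = 2 E d(X,Y) - E d(X,X') - E d(Y,Y').

    All expectations are means over all ordered pairs (the V-statistic
    convention), so identical point sets give exactly 0 and the statistic
    is nonnegative; with squared Euclidean distance it equals twice the
    squared distance between the group means."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    delta = _pairwise(X, Y, metric).mean()
    sx = _pairwise(X, X, metric).mean()
    sy = _pairwise(Y, Y, metric).mean()
    return float(2 * delta - sx - sy)


def _edist_from_sums(cross, within_g, within_c, n_g, n_c):
    return (
        2 * cross / (n_g * n_c)
        - within_g / (n_g * n_g)
        - within_c / (n_c * n_c)
    )


def energy_distance_test(
    layer: pd.DataFrame,
    labels: pd.Series,
    control_label: str,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Permutation energy-distance test of every group against controls.

    Per group: PCA (``n_pcs``) is fitted on the pooled group + control
    cells of ``layer``, the energy distance is computed on the PC scores,
    and the null is built by reshuffling the group/control split
    ``n_permutations`` times. P-values are Holm-Sidak adjusted across
    groups; ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    cfg = config or StatsConfig()
    labels = pd.Series(labels, index=layer.index)
    rng = np.random.default_rng(cfg.seed)
    ctrl_idx = labels.index[labels == control_label]
    if len(ctrl_idx) < 2:
        raise ValueError("need at least 2 control cells")
    groups = [g for g in labels.unique() if g != control_label]

    rows = []
    for g in groups:
        gi = labels.index[labels == g]
        if len(gi) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        X = layer.loc[list(gi) + list(ctrl_idx)].to_numpy(dtype=float)
        n_g, n = len(gi), len(gi) + len(ctrl_idx)
        n_c = n - n_g
        n_comp = min(cfg.n_pcs, X.shape[1], n - 1)
        pcs = PCA(n_components=n_comp, random_state=0).fit_transform(X)
        D = _pairwise(pcs, pcs, cfg.metric)
        Dtot = D.sum()

        m = np.zeros(n)
        m[:n_g] = 1.0
        obs = _stat_from_mask(D, Dtot, m, n_g, n_c)

        order = np.argsort(rng.random((cfg.n_permutations, n)), axis=1)
        M = np.zeros((cfg.n_permutations, n))
        np.put_along_axis(M, order[:, :n_g], 1.0, axis=1)
        A = M @ D
        within_g = (A * M).sum(axis=1)
        cross = (A * (1.0 - M)).sum(axis=1)
        within_c = Dtot - within_g - 2 * cross
        null = _edist_from_sums(cross, within_g, within_c, n_g, n_c)

        p = (1.0 + np.sum(null >= obs)) / (cfg.n_permutations + 1.0)
        rows.append({"group": g, "statistic": obs, "p": p, "n_cells": n_g})

    res = pd.DataFrame(rows)
    if len(res):
        reject, p_adj, *_ = multipletests(res["p"], alpha=cfg.alpha, method="holm-sidak")
        res["p_adj"] = p_adj
        res["significant"] = reject
        res["metric"] = cfg.metric
    return res


def _stat_from_mask(D, Dtot, m, n_g, n_c):
    a = m @ D
    within_g = float(a @ m)
    cross = float(a @ (1.0 - m))
    within_c = Dtot - within_g - 2 * cross
    return _edist_from_sums(cross, within_g, within_c, n_g, n_c)


# --------------------------------------------------------------------------
# differential expression


def differential_expression(
    layer: pd.DataFrame,
    group_mask,
    control_mask,
    alpha: float = 0.05,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per gene on tp10k-log values, BH-adjusted,
    with pseudobulk log2 fold-changes (means on the linear tp10k scale)."""
    group_mask = np.asarray(group_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if group_mask.sum() == 0 or control_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    x = layer.loc[group_mask].to_numpy(dtype=float)
    y = layer.loc[control_mask].to_numpy(dtype=float)
    stat, p = mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
    p = np.nan_to_num(p, nan=1.0)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    mg = np.expm1(x).mean(axis=0) + pseudocount
    mc = np.expm1(y).mean(axis=0) + pseudocount
    return pd.DataFrame(
        {
            "gene": layer.columns,
            "statistic": stat,
            "p": p,
            "p_adj": p_adj,
            "log2fc": np.log2(mg / mc),
            "significant": reject,
        }
    )


# --------------------------------------------------------------------------
# pseudobulk profiles


def pseudobulk_profiles(
    z_layer: pd.DataFrame,
    labels: pd.Series,
    control_label: str,
    top_n: int = 250,
    expression_layer: pd.DataFrame | None = None,
) -> tuple:
    """Per-group mean z profiles and their Pearson correlation matrix.

    Profiles are restricted to the ``top_n`` genes with highest control
    expression (ranked on ``expression_layer``, defaulting to the z layer's
    own control means) to suppress noise from low-expressed genes.
    """
    if top_n > z_layer.shape[1]:
        raise ValueError("top_n exceeds gene count")
    labels = pd.Series(labels, index=z_layer.index)
    ctrl = labels == control_label
    rank_layer = expression_layer if expression_layer is not None else z_layer
    rank_layer = rank_layer[z_layer.columns]
    support = (
        rank_layer.loc[ctrl].mean(axis=0).sort_values(ascending=False).index[:top_n]
    )
    groups = [g for g in labels.unique() if g != control_label]
    profiles = pd.DataFrame(
        {g: z_layer.loc[labels == g, support].mean(axis=0) for g in groups}
    ).T
    corr = profiles.T.corr(method="pearson")
    return profiles, corr


# --------------------------------------------------------------------------
# scores


def gene_set_score(
    z_layer: pd.DataFrame,
    gene_set,
    labels: pd.Series,
    control_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-guide mean z over a gene set, tested against controls.

    The score is the pseudobulk z-scored change relative to control cells
    averaged over the set. Significance: Mann-Whitney on per-cell set means
    versus control cells, Benjamini-Yekutieli adjusted across guides.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = sorted(set(gene_set) - set(z_layer.columns))
    if missing:
        raise ValueError(f"gene set members missing from panel: {missing}")
    labels = pd.Series(labels, index=z_layer.index)
    cell_score = z_layer[gene_set].mean(axis=1)
    ctrl_scores = cell_score[labels == control_label]
    rows = []
    for g in (g for g in labels.unique() if g != control_label):
        s = cell_score[labels == g]
        _, p = mannwhitneyu(s, ctrl_scores, alternative="two-sided")
        rows.append({"guide": g, "score": float(s.mean()), "p": float(p)})
    res = pd.DataFrame(rows)
    if len(res):
        reject, p_adj, *_ = multipletests(res["p"], alpha=alpha, method="fdr_by")
        res["p_adj"] = p_adj
        res["significant"] = reject
    return res


def zonation_score(
    z_layer: pd.DataFrame,
    markers: ZonationMarkers | None = None,
    split: bool = False,
):
    """Per-cell zonation score: sum of z over periportal markers minus sum
    over pericentral markers. ``split=True`` returns the two partial sums
    as a DataFrame instead."""
    m = markers or ZonationMarkers()
    missing = sorted(
        (set(m.periportal) | set(m.pericentral)) - set(z_layer.columns)
    )
    if missing:
        raise ValueError(f"zonation markers missing from panel: {missing}")
    pp = z_layer[list(m.periportal)].sum(axis=1)
    pc = z_layer[list(m.pericentral)].sum(axis=1)
    if split:
        return pd.DataFrame({"periportal": pp, "pericentral": pc})
    return pp - pc


def guide_zonation_scores(
    z_layer: pd.DataFrame,
    labels: pd.Series,
    control_label: str,
    markers: ZonationMarkers | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pseudobulk zonation score per guide with Mann-Whitney + BY testing."""
    labels = pd.Series(labels, index=z_layer.index)
    cell_score = zonation_score(z_layer, markers)
    ctrl = cell_score[labels == control_label]
    rows = []
    for g in (g for g in labels.unique() if g != control_label):
        s = cell_score[labels == g]
        _, p = mannwhitneyu(s, ctrl, alternative="two-sided")
        rows.append({"guide": g, "score": float(s.mean()), "p": float(p)})
    res = pd.DataFrame(rows)
    if len(res):
        reject, p_adj, *_ = multipletests(res["p"], alpha=alpha, method="fdr_by")
        res["p_adj"] = p_adj
        res["significant"] = reject
    return res


# --------------------------------------------------------------------------
# intensity effects


def intensity_effects(
    intensities: pd.DataFrame,
    labels: pd.Series,
    control_label: str,
    samples: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(guide, channel) z shift versus controls with BY correction.

    Channels are z-scored against the control mean and sd within each
    imaging sample, then concatenated; each guide-channel pair is tested
    with a two-sided Mann-Whitney against control cells.
    """
    labels = pd.Series(labels, index=intensities.index)
    if samples is None:
        samples = pd.Series("sample0", index=intensities.index)
    samples = pd.Series(samples, index=intensities.index)
    ctrl_mask = labels == control_label

    z_parts = []
    for s in samples.unique():
        sel = samples == s
        ctrl = intensities[sel & ctrl_mask]
        if len(ctrl) == 0:
            raise ValueError(f"no control cells in sample {s!r}")
        sd = ctrl.std(axis=0, ddof=0).replace(0, np.nan)
        z_parts.append((intensities[sel] - ctrl.mean(axis=0)) / sd)
    z = pd.concat(z_parts).loc[intensities.index]

    rows = []
    for g in (g for g in labels.unique() if g != control_label):
        for ch in intensities.columns:
            a = z.loc[labels == g, ch].dropna()
            b = z.loc[ctrl_mask, ch].dropna()
            _, p = mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {"guide": g, "channel": ch, "mean_z": float(a.mean()), "p": float(p)}
            )
    res = pd.DataFrame(rows)
    if len(res):
        reject, p_adj, *_ = multipletests(res["p"], alpha=alpha, method="fdr_by")
        res["p_adj"] = p_adj
        res["significant"] = reject
    return res
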