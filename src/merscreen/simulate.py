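"""Ground-truthed synthetic screens for a zonated liver lobule.

Emulates the study conditions of a pooled in vivo CRISPR screen read out by
amplified multiplexed FISH and by hybridization-based single-cell RNA-seq:

* a hepatocyte sheet with a zonal coordinate ``z`` in [0, 1] (0 pericentral,
  1 periportal) derived from planted central-vein and portal point sets,
  with subtypes Hep1..Hep6 as sextiles of ``z``;
* Poisson low-multiplicity lentiviral transduction (default MOI 0.3, inside
  the targeted 10-30% infection range), so most infected cells carry a
  single guide;
* a 202-target / 2-guides-per-target / 50-control guide library (454
  entries) with knockout effect templates: depletion of the targeted
  transcript (emulating nonsense-mediated decay), induction of a stress
  gene set, and zonal shifts;
* negative-binomial zonated counts, rendered amplicon bit-image stacks with
  per-bit flip noise, exact label masks, and Flex-style UMI tables with
  sgRNA spike-in probe counts.

Every rendered molecule, UMI, and image spot traces back to a ground-truth
record, and all generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook
from .stats import PERICENTRAL_MARKERS, PERIPORTAL_MARKERS

__all__ = [
    "GenePanel",
    "PerturbationLibrary",
    "SimulatedScreen",
    "build_panel_and_library",
    "simulate_tissue",
    "simulate_counts",
    "molecules_from_counts",
    "render_bit_images",
    "render_masks",
    "simulate_spot_intensities",
    "simulate_flex_counts",
    "GUIDE_PROBE_PREFIX",
]

GUIDE_PROBE_PREFIX = "probe:"
HEP_SUBTYPES = [f"Hep{i}" for i in range(1, 7)]


@dataclass
class GenePanel:
    """Gene panel with per-gene baseline abundance and zonal slope.

    Expected expression at zonal coordinate ``z`` is
    ``baseline * exp(slope * (z - 0.5))``: positive slopes are periportal,
    negative pericentral, zero flat.
    """

    genes: pd.DataFrame  # columns: name, baseline, zonal_slope
    stress_set: list = field(default_factory=list)

    def __post_init__(self):
        if (self.genes["baseline"] <= 0).any():
            raise ValueError("baseline abundances must be positive")
        missing = (set(PERIPORTAL_MARKERS) | set(PERICENTRAL_MARKERS)) - set(
            self.genes["name"]
        )
        if missing:
            raise ValueError(f"zonation marker genes missing from panel: {missing}")

    @property
    def names(self) -> list:
        return list(self.genes["name"])

    def zonal_factor(self, z: np.ndarray) -> np.ndarray:
        """(n_cells, n_genes) multiplicative zonal factor."""
        slopes = self.genes["zonal_slope"].to_numpy()
        return np.exp(np.outer(np.asarray(z) - 0.5, slopes))


@dataclass
class PerturbationLibrary:
    """Guide library: 2 guides per targeted gene plus negative controls.

    ``entries`` columns: guide, target_gene ('' for controls), is_control,
    template, depletion (multiplier on the targeted transcript), delta_z
    (additive zonal shift), set_fold (fold applied to the stress set).
    Controls carry the identity effect.
    """

    entries: pd.DataFrame
    stress_set: list = field(default_factory=list)

    def __post_init__(self):
        targeted = self.entries[~self.entries["is_control"]]
        per_gene = targeted.groupby("target_gene").size()
        if len(per_gene) and not (per_gene == per_gene.iloc[0]).all():
            raise ValueError("each targeted gene must have the same number of guides")

    @property
    def guides(self) -> list:
        return list(self.entries["guide"])

    @property
    def control_guides(self) -> list:
        return list(self.entries.loc[self.entries["is_control"], "guide"])

    def row(self, guide: str) -> pd.Series:
        return self.entries.set_index("guide").loc[guide]


def build_panel_and_library(
    n_genes: int = 209,
    zonated_fraction: float = 0.4,
    n_targets: int = 202,
    guides_per_target: int = 2,
    n_controls: int = 50,
    depletion: float = 0.2,
    geneset_fold: float = 2.0,
    delta_z: float = 0.25,
    template_cycle: tuple = ("depletion",) * 8 + ("geneset",) + ("zonal",),
    seed: int = 0,
) -> tuple:
    """Seeded construction of a gene panel and guide library.

    The panel always contains the 23 zonation marker genes (7 periportal,
    16 pericentral) with matching slope signs, plus a 10-gene stress set
    used by the gene-set induction template. Defaults follow the screen's
    stated design: 202 targeted genes, two independent sgRNAs each, and 50
    negative control sgRNAs (454 library entries).
    """
    rng = np.random.default_rng(seed)
    markers = list(PERIPORTAL_MARKERS) + list(PERICENTRAL_MARKERS)
    n_stress = 10
    n_other = n_genes - len(markers) - n_stress
    if n_other < 0:
        raise ValueError(f"n_genes must be >= {len(markers) + n_stress}")
    stress_set = [f"stress_{i:02d}" for i in range(n_stress)]
    other = [f"gene_{i:04d}" for i in range(n_other)]
    names = markers + stress_set + other

    baselines = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=n_genes)
    slopes = np.zeros(n_genes)
    slopes[: len(PERIPORTAL_MARKERS)] = rng.uniform(1.0, 2.0, len(PERIPORTAL_MARKERS))
    slopes[len(PERIPORTAL_MARKERS) : len(markers)] = -rng.uniform(
        1.0, 2.0, len(PERICENTRAL_MARKERS)
    )
    n_extra_zonated = max(0, int(round(zonated_fraction * n_genes)) - len(markers))
    zon_idx = len(markers) + n_stress + np.arange(min(n_extra_zonated, n_other))
    slopes[zon_idx] = rng.uniform(-1.5, 1.5, len(zon_idx))

    panel = GenePanel(
        genes=pd.DataFrame(
            {"name": names, "baseline": baselines, "zonal_slope": slopes}
        ),
        stress_set=stress_set,
    )

    if n_targets > n_genes:
        raise ValueError("n_targets must be <= n_genes")
    # prefer non-stress-set targets so the gene-set induction template stays
    # orthogonal to its readout, falling back to the full panel when needed
    target_pool = [n for n in names if n not in stress_set]
    if n_targets > len(target_pool):
        target_pool = names
    targets = list(rng.choice(target_pool, size=n_targets, replace=False))
    rows = []
    for t_i, gene in enumerate(targets):
        template = template_cycle[t_i % len(template_cycle)]
        for g_i in range(guides_per_target):
            rows.append(
                {
                    "guide": f"sg{gene}_{g_i + 1}",
                    "target_gene": gene,
                    "is_control": False,
                    "template": template,
                    "depletion": depletion,
                    "delta_z": (
                        delta_z * (1 if t_i % 2 == 0 else -1)
                        if template == "zonal"
                        else 0.0
                    ),
                    "set_fold": geneset_fold if template == "geneset" else 1.0,
                }
            )
    for c_i in range(n_controls):
        rows.append(
            {
                "guide": f"sgCtrl_{c_i + 1:02d}",
                "target_gene": "",
                "is_control": True,
                "template": "control",
                "depletion": 1.0,
                "delta_z": 0.0,
                "set_fold": 1.0,
            }
        )
    library = PerturbationLibrary(entries=pd.DataFrame(rows), stress_set=stress_set)
    return panel, library


@dataclass
class SimulatedScreen:
    """Container tying together every layer of a synthetic screen."""

    cells: pd.DataFrame  # cell_id, x, y, radius, z, subtype, guides (tuple)
    library: PerturbationLibrary | None = None
    panel: GenePanel | None = None
    true_counts: pd.DataFrame | None = None
    molecules: pd.DataFrame | None = None
    images: np.ndarray | None = None
    masks: np.ndarray | None = None
    flex_umis: pd.DataFrame | None = None
    pixel_size_um: float | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)


def simulate_tissue(
    library: PerturbationLibrary,
    n_cells: int = 10_000,
    field_um: float = 1000.0,
    moi: float = 0.3,
    lobule_grid: int = 2,
    jitter: float = 0.15,
    clone_prob: float = 0.0,
    seed: int = 0,
) -> SimulatedScreen:
    """Place cells on a jittered grid, compute zonal coordinates, and draw
    Poisson(MOI) barcode multisets.

    The zonal coordinate is ``z = d_cv / (d_cv + d_pv)`` where ``d_cv`` and
    ``d_pv`` are distances to planted central-vein (lobule centers) and
    portal (lobule corners) point sets; the subtype is the sextile of ``z``
    (Hep1 lowest, i.e. most pericentral). With probability ``clone_prob`` a
    cell copies the barcode multiset of its left neighbor, emulating clonal
    patches from postnatal proliferation of single transduced hepatocytes.
    """
    if moi <= 0:
        raise ValueError("moi must be > 0")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    spacing = field_um / side
    ix, iy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    x = (ix.ravel() + 0.5) * spacing
    y = (iy.ravel() + 0.5) * spacing
    x = (x + rng.uniform(-jitter, jitter, x.size) * spacing)[:n_cells]
    y = (y + rng.uniform(-jitter, jitter, y.size) * spacing)[:n_cells]
    if jitter >= 0.5:
        raise ValueError("jitter must be < 0.5 grid spacings")
    # radius chosen so disks are disjoint for any jitter draw (masks must
    # partition cell interiors exactly)
    radius = np.full(n_cells, 0.9 * (0.5 - jitter) * spacing)

    g = lobule_grid
    cv = np.array(
        [[(i + 0.5) * field_um / g, (j + 0.5) * field_um / g]
         for i in range(g) for j in range(g)]
    )
    pv = np.array(
        [[i * field_um / g, j * field_um / g]
         for i in range(g + 1) for j in range(g + 1)]
    )
    pts = np.column_stack([x, y])
    d_cv, _ = cKDTree(cv).query(pts)
    d_pv, _ = cKDTree(pv).query(pts)
    z = d_cv / (d_cv + d_pv)

    subtype_idx = np.minimum((z * 6).astype(int), 5)
    subtype = np.array(HEP_SUBTYPES)[subtype_idx]

    guides = np.array(library.guides)
    n_bc = rng.poisson(moi, n_cells)
    cell_guides = [
        tuple(rng.choice(guides, size=k, replace=True)) for k in n_bc
    ]
    if clone_prob > 0:
        copy = rng.random(n_cells) < clone_prob
        for i in np.flatnonzero(copy):
            if i > 0:
                cell_guides[i] = cell_guides[i - 1]

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "x": x,
            "y": y,
            "radius": radius,
            "z": z,
            "subtype": subtype,
            "guides": cell_guides,
        }
    )
    return SimulatedScreen(
        cells=cells,
        library=library,
        seed=seed,
        params={"field_um": field_um, "moi": moi, "lobule_grid": lobule_grid},
    )


def _effective_z(screen: SimulatedScreen, lib_idx: pd.DataFrame) -> np.ndarray:
    dz = np.array(
        [
            sum(lib_idx.loc[g, "delta_z"] for g in gs) if gs else 0.0
            for gs in screen.cells["guides"]
        ]
    )
    return np.clip(screen.cells["z"].to_numpy() + dz, 0.0, 1.0)


def simulate_counts(
    screen: SimulatedScreen,
    panel: GenePanel,
    library: PerturbationLibrary | None = None,
    mean_library_size: float = 300.0,
    dispersion: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial cell-by-gene counts.

    Per-cell means are ``baseline * zonal_factor(z_eff) * perturbation
    fold-changes``; the targeted gene is additionally multiplied by its
    depletion factor. ``dispersion`` is the NB overdispersion (0 gives
    Poisson). Baselines are scaled so an unperturbed mid-lobule cell has
    ``mean_library_size`` expected molecules.
    """
    library = library if library is not None else screen.library
    rng = np.random.default_rng(seed)
    lib_idx = library.entries.set_index("guide")
    names = panel.names
    col = {n: j for j, n in enumerate(names)}

    base = panel.genes["baseline"].to_numpy()
    base = base / base.sum() * mean_library_size
    z_eff = _effective_z(screen, lib_idx)
    mu = base[None, :] * panel.zonal_factor(z_eff)

    set_cols = [col[g] for g in library.stress_set if g in col]
    for i, gs in enumerate(screen.cells["guides"]):
        for g in gs:
            row = lib_idx.loc[g]
            tgt = row["target_gene"]
            if tgt and tgt in col:
                mu[i, col[tgt]] *= row["depletion"]
            if row["set_fold"] != 1.0 and set_cols:
                mu[i, set_cols] *= row["set_fold"]

    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, columns=names)
    df.insert(0, "cell_id", screen.cells["cell_id"].to_numpy())
    df = df.set_index("cell_id")
    screen.panel = panel
    screen.true_counts = df
    return df


def molecules_from_counts(
    screen: SimulatedScreen,
    counts: pd.DataFrame | None = None,
    min_separation_um: float = 0.0,
    edge_margin_um: float = 0.5,
    max_tries: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Place each counted molecule uniformly inside its cell's disk.

    ``min_separation_um`` enforces a minimum pairwise distance within each
    cell by rejection (used for noiseless end-to-end identity checks where
    every amplicon must resolve into its own spot); ``edge_margin_um``
    keeps molecules off the disk boundary so a detected peak pixel cannot
    quantize onto background.
    """
    counts = counts if counts is not None else screen.true_counts
    rng = np.random.default_rng(seed)
    genes = list(counts.columns)
    rows = []
    cells = screen.cells.set_index("cell_id")
    for cell_id, row in counts.iterrows():
        cx, cy, r = cells.loc[cell_id, ["x", "y", "radius"]]
        r = max(r - edge_margin_um, 0.5 * r)
        placed: list = []
        for gene in genes:
            for _ in range(int(row[gene])):
                for _try in range(max_tries):
                    rho = r * np.sqrt(rng.random())
                    theta = rng.uniform(0, 2 * np.pi)
                    mx, my = cx + rho * np.cos(theta), cy + rho * np.sin(theta)
                    if min_separation_um <= 0 or all(
                        (mx - px) ** 2 + (my - py) ** 2 >= min_separation_um**2
                        for px, py in placed
                    ):
                        break
                placed.append((mx, my))
                rows.append({"x": mx, "y": my, "gene": gene, "cell_id": cell_id})
    mol = pd.DataFrame(rows, columns=["x", "y", "gene", "cell_id"])
    screen.molecules = mol
    return mol


def _gaussian_stamp(images, plane, x_px, y_px, amp, sigma_px):
    h, w = images.shape[1:]
    rad = max(1, int(np.ceil(3 * sigma_px)))
    x0, y0 = int(round(x_px)), int(round(y_px))
    xs = np.arange(max(0, x0 - rad), min(w, x0 + rad + 1))
    ys = np.arange(max(0, y0 - rad), min(h, y0 + rad + 1))
    if not len(xs) or not len(ys):
        return
    dx = xs[None, :] - x_px
    dy = ys[:, None] - y_px
    images[plane, ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] += amp * np.exp(
        -(dx**2 + dy**2) / (2 * sigma_px**2)
    )


def render_bit_images(
    screen: SimulatedScreen,
    codebook: Codebook,
    gene_to_codeword: dict,
    pixel_size_um: float = 0.25,
    psf_sigma_um: float = 0.3,
    brightness_sigma: float = 0.25,
    p_on_to_off: float = 0.04,
    p_off_to_on: float = 0.01,
    blank_rate: float = 0.0,
    background_sigma: float = 0.02,
    seed: int = 0,
) -> tuple:
    """Render molecules into a per-bit image stack with flip noise.

    Each molecule becomes a Gaussian spot (lognormal brightness, shared
    across its on-bits) in every plane of its codeword after per-bit flips
    (``p_on_to_off`` / ``p_off_to_on``). Spurious blank-codeword molecules
    are injected at ``blank_rate`` (fraction of the molecule count) uniform
    over the field. Returns ``(images, truth)`` where ``truth`` extends the
    molecule table with the codeword, realized bits, and brightness.
    """
    if screen.molecules is None:
        raise ValueError("run molecules_from_counts first")
    rng = np.random.default_rng(seed)
    field = screen.params.get("field_um", float(screen.cells[["x", "y"]].max().max()))
    npx = int(np.ceil(field / pixel_size_um))
    images = np.zeros((codebook.n_bits, npx, npx), dtype=np.float32)
    bitmat = codebook.bit_matrix
    index_of = {cw.index: i for i, cw in enumerate(codebook.codewords)}

    mol = screen.molecules.copy()
    mol["codeword_index"] = mol["gene"].map(gene_to_codeword)
    if mol["codeword_index"].isna().any():
        missing = sorted(mol.loc[mol["codeword_index"].isna(), "gene"].unique())
        raise ValueError(f"molecule genes without codewords: {missing}")

    n_blank = int(round(blank_rate * len(mol)))
    blanks = codebook.blank_indices
    if n_blank and not blanks:
        raise ValueError("blank_rate > 0 but the codebook has no blank codewords")
    if n_blank:
        extra = pd.DataFrame(
            {
                "x": rng.uniform(0, field, n_blank),
                "y": rng.uniform(0, field, n_blank),
                "gene": "__blank__",
                "cell_id": 0,
                "codeword_index": rng.choice(blanks, n_blank),
            }
        )
        mol = pd.concat([mol, extra], ignore_index=True)

    sigma_px = psf_sigma_um / pixel_size_um
    realized_bits = []
    brightness = rng.lognormal(mean=0.0, sigma=brightness_sigma, size=len(mol))
    for i, row in enumerate(mol.itertuples()):
        bits = bitmat[index_of[int(row.codeword_index)]].astype(bool).copy()
        flips_off = rng.random(codebook.n_bits) < p_on_to_off
        flips_on = rng.random(codebook.n_bits) < p_off_to_on
        bits = np.where(bits, ~flips_off, flips_on)
        realized_bits.append("".join("1" if b else "0" for b in bits))
        x_px, y_px = row.x / pixel_size_um, row.y / pixel_size_um
        for plane in np.flatnonzero(bits):
            _gaussian_stamp(images, plane, x_px, y_px, brightness[i], sigma_px)

    if background_sigma > 0:
        images += np.abs(
            rng.normal(0.0, background_sigma, images.shape).astype(np.float32)
        )

    mol["realized_bits"] = realized_bits
    mol["brightness"] = brightness
    screen.images = images
    screen.pixel_size_um = pixel_size_um
    screen.molecules = mol
    return images, mol


def render_masks(
    screen: SimulatedScreen, pixel_size_um: float | None = None
) -> np.ndarray:
    """Exact 16-bit label image of the cell disks (0 = background)."""
    pixel_size_um = pixel_size_um or screen.pixel_size_um or 0.25
    field = screen.params.get("field_um", float(screen.cells[["x", "y"]].max().max()))
    npx = int(np.ceil(field / pixel_size_um))
    masks = np.zeros((npx, npx), dtype=np.uint16)
    for row in screen.cells.itertuples():
        cx, cy, r = row.x / pixel_size_um, row.y / pixel_size_um, row.radius / pixel_size_um
        x0, x1 = max(0, int(cx - r) - 1), min(npx, int(cx + r) + 2)
        y0, y1 = max(0, int(cy - r) - 1), min(npx, int(cy + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        masks[y0:y1, x0:x1][inside] = row.cell_id
    screen.masks = masks
    return masks


def simulate_spot_intensities(
    n_molecules: int,
    codebook: Codebook,
    p_on_to_off: float = 0.04,
    p_off_to_on: float = 0.01,
    brightness_sigma: float = 0.25,
    bit_jitter_sigma: float = 0.1,
    off_level: float = 0.05,
    blank_rate: float = 0.0,
    gene_probs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple:
    """Per-molecule spot intensity vectors without image rendering.

    The desk-scale stand-in for detecting ~10^4-10^5 amplicons from images:
    each molecule draws a coding codeword (optionally blank at
    ``blank_rate``), per-bit flips are applied, on-bits get a shared
    lognormal brightness with per-bit jitter, off-bits get low-level
    background. Returns ``(intensities, areas, truth)``.
    """
    rng = np.random.default_rng(seed)
    coding = codebook.coding_indices or [cw.index for cw in codebook.codewords]
    blanks = codebook.blank_indices
    index_of = {cw.index: i for i, cw in enumerate(codebook.codewords)}
    bitmat = codebook.bit_matrix.astype(bool)

    if gene_probs is not None:
        gene_probs = np.asarray(gene_probs, dtype=float)
        gene_probs = gene_probs / gene_probs.sum()
    chosen = rng.choice(coding, size=n_molecules, p=gene_probs)
    if blank_rate > 0 and blanks:
        is_blank = rng.random(n_molecules) < blank_rate
        chosen[is_blank] = rng.choice(blanks, is_blank.sum())

    rows = np.array([index_of[int(c)] for c in chosen])
    bits = bitmat[rows].copy()
    flips_off = rng.random(bits.shape) < p_on_to_off
    flips_on = rng.random(bits.shape) < p_off_to_on
    realized = np.where(bits, ~flips_off, flips_on)

    brightness = rng.lognormal(0.0, brightness_sigma, n_molecules)
    jitter = rng.lognormal(0.0, bit_jitter_sigma, bits.shape)
    background = np.abs(rng.normal(0.0, off_level, bits.shape))
    intensities = np.where(realized, brightness[:, None] * jitter, 0.0) + background
    areas = np.maximum(1, np.round(9 + 6 * brightness + rng.normal(0, 1, n_molecules)))

    truth = pd.DataFrame(
        {
            "true_codeword_index": chosen,
            "true_is_blank": [codebook.is_blank(int(c)) for c in chosen],
            "true_name": [codebook.name_of(int(c)) for c in chosen],
            "n_flips": (realized != bits).sum(axis=1)
            + np.abs(bits.astype(int) - bitmat[rows].astype(int)).sum(axis=1),
            "brightness": brightness,
        }
    )
    truth["n_flips"] = (realized != bitmat[rows]).sum(axis=1)
    return intensities, areas.astype(int), truth


def simulate_flex_counts(
    screen: SimulatedScreen,
    capture_efficiency: float = 0.5,
    guide_mean: float = 50.0,
    ambient_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Flex-style UMI table: thinned transcriptome plus sgRNA probe counts.

    Transcriptome UMIs are a binomial thinning of the true counts at
    ``capture_efficiency``. Each cell's true guide(s) receive
    Poisson(``guide_mean``) spike-in probe UMIs; every other guide probe
    receives Poisson(``ambient_rate``) ambient counts, reproducing the
    bimodal UMI histograms used to threshold sgRNA calls.
    """
    if screen.true_counts is None:
        raise ValueError("run simulate_counts first")
    rng = np.random.default_rng(seed)
    counts = screen.true_counts
    umis = rng.binomial(counts.to_numpy(), capture_efficiency)
    flex = pd.DataFrame(umis, index=counts.index, columns=counts.columns)

    guides = screen.library.guides
    probe = rng.poisson(ambient_rate, size=(len(flex), len(guides)))
    gcol = {g: j for j, g in enumerate(guides)}
    for i, gs in enumerate(screen.cells["guides"]):
        for g in gs:
            probe[i, gcol[g]] += rng.poisson(guide_mean)
    probe_df = pd.DataFrame(
        probe, index=counts.index, columns=[GUIDE_PROBE_PREFIX + g for g in guides]
    )
    flex = pd.concat([flex, probe_df], axis=1)
    screen.flex_umis = flex
    return flex


def guide_probe_columns(flex: pd.DataFrame) -> list:
    return [c for c in flex.columns if c.startswith(GUIDE_PROBE_PREFIX)]
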