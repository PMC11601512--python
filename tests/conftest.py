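"""Shared fixtures: codebooks, panels, and small rendered screens."""

import numpy as np
import pytest

from merscreen import codebook as cb
from merscreen import simulate as sim


@pytest.fixture(scope="session")
def gene_codebook():
    """21-bit HW4 MHD4 codebook, unassigned."""
    return cb.generate_constant_weight_code(21, 4, 4, 209, seed=0)


@pytest.fixture(scope="session")
def barcode_codebook():
    """18-bit HW6 MHD4 codebook, unassigned."""
    return cb.generate_constant_weight_code(18, 6, 4, 456, seed=0)


@pytest.fixture(scope="session")
def panel_library():
    return sim.build_panel_and_library(seed=0)


@pytest.fixture(scope="session")
def assigned_codebook(gene_codebook, panel_library):
    """Gene codebook with the default panel assigned plus ~10% blanks."""
    panel, _ = panel_library
    book = cb.assign_targets(gene_codebook, panel.names, n_blanks=21, seed=0)
    return book.used()


@pytest.fixture(scope="session")
def noiseless_screen(panel_library, assigned_codebook):
    """Small rendered screen with zero noise: every amplicon resolvable."""
    panel, library = panel_library
    screen = sim.simulate_tissue(library, n_cells=9, field_um=90, moi=0.3, seed=2)
    sim.simulate_counts(screen, panel, mean_library_size=15, seed=3)
    sim.molecules_from_counts(screen, min_separation_um=2.0, seed=4)
    g2c = {name: idx for idx, name in assigned_codebook.target_names.items()}
    sim.render_bit_images(
        screen,
        assigned_codebook,
        g2c,
        p_on_to_off=0.0,
        p_off_to_on=0.0,
        background_sigma=0.0,
        brightness_sigma=0.0,
        seed=5,
    )
    sim.render_masks(screen)
    return screen


@pytest.fixture(scope="session")
def noisy_spots(assigned_codebook):
    """20k simulated spot intensity vectors at harsh flip noise.

    Flip rates are set well above the defaults so that blank calls are
    plentiful enough to exercise the misidentification filter at this n.
    """
    intens, areas, truth = sim.simulate_spot_intensities(
        20_000, assigned_codebook, p_on_to_off=0.12, p_off_to_on=0.05, seed=7
    )
    return intens, areas, truth
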