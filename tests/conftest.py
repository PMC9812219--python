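"""Shared fixtures: small seeded synthetic scenes."""

import numpy as np
import pytest

import cryotarget as ct


@pytest.fixture(scope="session")
def grid_scene():
    """Axis-aligned 4x4 mesh, clean contrast."""
    spec = ct.GridSceneSpec(256, 256, mesh_pitch_px=64, square_side_px=40,
                            rotation_deg=0.0, bar_rate=4, square_rate=40, seed=1)
    return ct.generate_grid_scene(spec)


@pytest.fixture(scope="session")
def rotated_grid_scene():
    spec = ct.GridSceneSpec(256, 256, mesh_pitch_px=64, square_side_px=40,
                            rotation_deg=30.0, bar_rate=4, square_rate=40, seed=2)
    return ct.generate_grid_scene(spec)


@pytest.fixture(scope="session")
def hole_scene():
    """Clean 4x4 hole lattice, no dropout or contamination."""
    spec = ct.HoleSceneSpec(128, 128, lattice_pitch_px=32, hole_radius_px=8,
                            lattice_origin_px=(16.0, 16.0), noise_sd=0.1, seed=3)
    return ct.generate_hole_scene(spec)


@pytest.fixture(scope="session")
def messy_hole_scene():
    """Hole scene with dropout and contamination."""
    spec = ct.HoleSceneSpec(128, 128, lattice_pitch_px=32, hole_radius_px=8,
                            lattice_origin_px=(20.0, 12.0), noise_sd=0.15,
                            n_contaminants=2, dropout_fraction=0.3, seed=4)
    return ct.generate_hole_scene(spec)


@pytest.fixture(scope="session")
def clean_probability_map(hole_scene):
    return ct.generate_probability_map(hole_scene, blob_sigma=3.0,
                                       n_spurious=0, seed=5)
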