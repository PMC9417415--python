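"""Shared fixtures: small planted designs and their ground-truth tables."""

import logging

import pytest

import ecogrowth as eg

# extraction-window warnings are expected on deliberately degraded curves
logging.getLogger("ecogrowth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_design() -> eg.MediumDesign:
    """Ten components, six levels, four backgrounds (240 combinations)."""
    return eg.generate_design(n_components=10, levels_per_gradient=6,
                              n_backgrounds=4, seed=2)


@pytest.fixture(scope="session")
def planted_model() -> eg.ResponseModel:
    """Noise-free planted map with one determinant per growth parameter."""
    return eg.ResponseModel(
        determinant_map={"tau": "alanine", "rate": "glutamine",
                         "capacity": "glycine"},
        noise_sd=0.0)


@pytest.fixture(scope="session")
def truth_table(small_design, planted_model):
    return eg.ground_truth_parameters(small_design, planted_model)


#: A small grid usable for fast boosted-tree searches in tests.
FAST_GRID = {"learning_rate": [0.1, 0.3], "max_depth": [2, 3]}
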