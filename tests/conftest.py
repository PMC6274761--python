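"""Shared fixtures: session-scoped synthetic inputs so expensive generation
and calibration run once."""

from __future__ import annotations

import numpy as np
import pytest

from idpcoev.scoring import fit_default_calibration
from idpcoev.seqprep import sequence_weights
from idpcoev.synthetic import (GeometryConfig, SynthConfig, generate_complex,
                               generate_paired_msa)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    """Small synthetic complex: 25-residue helical IDP on a 40-residue
    three-helix-bundle partner, two strong planted couplings."""
    return SynthConfig(
        n_species=300, len_idp=25, len_partner=40,
        planted_pairs=((5, 12, 0.9), (20, 28, 0.9)), seed=3,
        geometry=GeometryConfig(idp_conformation="helix",
                                contact_distance_max=5.0),
    )


@pytest.fixture(scope="session")
def synth_msa(synth_config):
    aln, truth = generate_paired_msa(synth_config)
    aln.weights = sequence_weights(aln)
    return aln, truth


@pytest.fixture(scope="session")
def synth_complex(synth_config, synth_msa):
    _, truth = synth_msa
    return generate_complex(synth_config, truth)


@pytest.fixture(scope="session")
def calibration():
    return fit_default_calibration(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
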