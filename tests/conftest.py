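import numpy as np
import pytest

from turnprop.reference_data import get_ideal_angles
from turnprop.synthetic_data import ConformerSpec, EnsembleSpec, simulate_ensemble

HEPTA_SEQUENCE = ("ALA", "ALA", "ASN", "GLY", "ALA", "ALA")


@pytest.fixture(scope="session")
def iprime_coil_ensemble():
    """30% ideal-I' Asn-Gly turn / 70% coil, 20k frames, fixed seed."""
    spec = EnsembleSpec(
        sequence=HEPTA_SEQUENCE,
        conformers=(
            ConformerSpec("turn_Iprime", 0.3, window_start=2,
                          central_angles=get_ideal_angles("I'")),
            ConformerSpec("coil", 0.7),
        ),
        kappa=50.0,
        n_frames=20000,
        seed=42,
    )
    return simulate_ensemble(spec)


@pytest.fixture(scope="session")
def two_conformer_ensemble():
    """Two point-like conformers (70/30), for dPCA recovery checks."""
    spec = EnsembleSpec(
        sequence=HEPTA_SEQUENCE,
        conformers=(
            ConformerSpec("A", 0.7, window_start=2,
                          central_angles=get_ideal_angles("I'"),
                          flank_angle_mode="fixed"),
            ConformerSpec("B", 0.3, window_start=2,
                          central_angles=get_ideal_angles("I"),
                          flank_angle_mode="fixed"),
        ),
        kappa=400.0,
        n_frames=20000,
        seed=7,
    )
    return simulate_ensemble(spec)


@pytest.fixture(scope="session")
def small_ensemble():
    """Small mixed ensemble with temperatures, for I/O and CLI checks."""
    spec = EnsembleSpec(
        sequence=HEPTA_SEQUENCE,
        conformers=(
            ConformerSpec("turn", 0.6, window_start=2,
                          central_angles=get_ideal_angles("I'"),
                          flank_angle_mode="fixed"),
            ConformerSpec("coil", 0.4),
        ),
        kappa=50.0,
        n_frames=200,
        seed=11,
        temperature_model=(380.0, 100.0),
    )
    return simulate_ensemble(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
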