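import numpy as np
import pytest

from pemlearn.representations import Geometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def formaldehyde_like():
    """Planar CH2O-like toy geometry (Å), H atoms deliberately out of
    canonical order (H at index 2 is the farther one)."""
    return Geometry(
        atom_labels=("C", "O", "H", "H"),
        coords=np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 1.2],
                [1.06, 0.0, -0.65],  # r(C-H) = 1.24
                [-0.87, 0.0, -0.5],  # r(C-H) = 1.00
            ]
        ),
    )


@pytest.fixture
def water_modes():
    """Synthetic water-like normal modes: random orthonormal mass-weighted
    displacement vectors with realistic frequencies/reduced masses."""
    from pemlearn.wigner import NormalModeSet

    rng = np.random.default_rng(7)
    ref = Geometry(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    )
    masses = np.array([15.999, 1.00794, 1.00794])
    q, _ = np.linalg.qr(rng.normal(size=(9, 3)))
    mw = q.T.reshape(3, 3, 3)
    displacements = mw / np.sqrt(masses)[None, :, None]
    return NormalModeSet(
        frequencies_cm1=np.array([1600.0, 3650.0, 3750.0]),
        reduced_masses=np.array([1.08, 1.04, 1.08]),
        displacements=displacements,
        reference=ref,
        masses=masses,
    )
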