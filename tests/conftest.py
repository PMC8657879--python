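import numpy as np
import pytest

from foldcv.fixtures import InternalCoordSpec, build_backbone

# Survey mean dihedrals of the alpha-helix (H) category.
HELIX_PHI, HELIX_PSI = -64.70, -39.56
# Survey mean dihedrals of the extended-strand (E) category.
SHEET_PHI, SHEET_PSI = -110.89, 122.38


def ang_diff(a, b):
    """Signed circular difference a-b in degrees, NaN-propagating."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


def make_chain(phi, psi, omega, **kw):
    return build_backbone(InternalCoordSpec(phi=phi, psi=psi, omega=omega, **kw))


@pytest.fixture
def helix_chain():
    """20-residue ideal alpha-helix backbone."""
    n = 20
    return make_chain(
        np.full(n, HELIX_PHI), np.full(n, HELIX_PSI), np.full(n, 180.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210923)
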