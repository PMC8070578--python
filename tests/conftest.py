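import numpy as np
import pytest

from parscore.geometry import ArchLandmarks, Landmark


def make_landmark(fdi, name, x, y, z):
    return Landmark(fdi, name, np.array([float(x), float(y), float(z)]))


def make_arches(upper_specs, lower_specs, upper_flags=None, lower_flags=None):
    """Build an upper/lower arch pair from (fdi, name, x, y, z) tuples."""

    def build(arch, specs, flags):
        lms = [make_landmark(*s) for s in specs]
        teeth = {lm.tooth_id for lm in lms} | set(flags or {})
        return ArchLandmarks(arch, lms, teeth, flags or {})

    return build("upper", upper_specs, upper_flags), build("lower", lower_specs, lower_flags)


@pytest.fixture
def flat_arches():
    """Minimal coplanar arch pair: plane anchors at z=0, incisors toward +y.

    Anchor cusps sit at the default anchor teeth (first premolars and first
    molars of all four quadrants); lower central incisor edges and lower first
    molar cusps orient the sagittal axis.
    """
    upper = [
        (14, "buccal_cusp", -22, 25, 0),
        (24, "buccal_cusp", 22, 25, 0),
        (16, "buccal_cusp", -28, 5, 0),
        (26, "buccal_cusp", 28, 5, 0),
        # non-anchor landmarks above the plane fix the normal's orientation
        (11, "mesial_contact", -0.5, 41, 1),
        (21, "mesial_contact", 0.5, 41, 1),
    ]
    lower = [
        (44, "buccal_cusp", -20, 24, 0),
        (34, "buccal_cusp", 20, 24, 0),
        (46, "buccal_cusp", -26, 4, 0),
        (36, "buccal_cusp", 26, 4, 0),
        (41, "incisal_edge", -3, 40, 0),
        (31, "incisal_edge", 3, 40, 0),
    ]
    return make_arches(upper, lower)


def random_rigid_transform(rng):
    """Uniformly random rotation (QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-50, 50, size=3)
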