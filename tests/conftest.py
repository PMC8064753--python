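import numpy as np
import pytest

import granulekit as gk


@pytest.fixture(scope="session")
def equal_amp_scene():
    """10 equal-amplitude granules, noise-free, in the packed-soma scene."""
    return gk.random_scene(10, seed=5, amplitude_range=(300.0, 300.0))


@pytest.fixture(scope="session")
def equal_amp_field(equal_amp_scene):
    return gk.generate_field(equal_amp_scene, seed=5)


def ring_template(spec):
    """Independent re-rendering of the noise-free cell template.

    Used as an oracle against the generator: per-pixel membership is
    evaluated directly from the ring descriptors.
    """
    h, w = spec.field_shape
    img = np.full((h, w), spec.background_level, dtype=float)
    rr, cc = np.mgrid[0:h, 0:w]
    soma = np.zeros((h, w), bool)
    nuc = np.zeros((h, w), bool)
    for cell in spec.cells:
        d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
        soma |= d2 <= cell.outer_radius**2
        nuc |= d2 < cell.inner_radius**2
    img[soma] = spec.cytoplasm_level
    img[nuc] = spec.background_level
    return img


def match_to_truth(centroids, true_centers, max_dist=3.0):
    """Pair detected centroids with nearest ground-truth centers."""
    true_centers = np.asarray(true_centers, dtype=float)
    pairs = []
    for i, c in enumerate(np.asarray(centroids, dtype=float)):
        d = np.hypot(true_centers[:, 0] - c[0], true_centers[:, 1] - c[1])
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            pairs.append((i, j))
    return pairs
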