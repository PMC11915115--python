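import numpy as np
import pytest

from aidp.gradients import D_WATER, make_scheme


@pytest.fixture(scope="session")
def scheme():
    """Protocol-like single-shell scheme: 30 directions, 5 b0, b=1000."""
    return make_scheme(n_directions=30, n_b0=5, b_value=1000.0, seed=3)


def two_compartment_signal(grad, fw, tensor, s0=1.0, d_water=D_WATER):
    """Noiseless forward model for a single voxel."""
    b, g = grad.bvals, grad.bvecs
    quad = np.einsum("ni,ij,nj->n", g, tensor, g)
    return s0 * ((1 - fw) * np.exp(-b * quad) + fw * np.exp(-b * d_water))


def axial_tensor(fa, md=0.7e-3, axis=0):
    """Axially symmetric tensor with exact FA and MD along a coordinate axis."""
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lams = np.full(3, md * (1 - a))
    lams[axis] = md * (1 + 2 * a)
    return np.diag(lams)
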