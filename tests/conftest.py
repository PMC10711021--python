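import numpy as np
import pytest

from particlesieve import (
    CTFParams,
    ParticleRecord,
    ParticleStack,
    Pose,
    FourierProjector,
    forward_project,
    make_phantom,
)


@pytest.fixture(scope="session")
def smooth_volume():
    """Small smooth blob phantom (few large blobs) for interpolation oracles."""
    return make_phantom("gaussian_blobs", 32, 1.0, seed=0,
                        n_blobs=8, blob_sigma_frac=(0.05, 0.11))


@pytest.fixture(scope="session")
def projection_stack(smooth_volume):
    """500 noise-free CTF-free projections at uniform random poses."""
    rng = np.random.default_rng(1)
    L = smooth_volume.edge
    proj = FourierProjector(smooth_volume)
    n = 500
    imgs = np.empty((n, L, L), dtype=np.float32)
    recs = []
    for i in range(n):
        pose = Pose(rot=rng.uniform(0, 360),
                    tilt=np.degrees(np.arccos(rng.uniform(-1, 1))),
                    psi=rng.uniform(0, 360))
        imgs[i] = forward_project(smooth_volume, pose, None, projector=proj)
        recs.append(ParticleRecord(image_index=i, pose=pose, ctf=None,
                                   half_set=1 + i % 2))
    return ParticleStack(images=imgs, pixel_size=smooth_volume.voxel_size,
                         records=recs)


@pytest.fixture
def ctf_params():
    return CTFParams(voltage=300.0, cs=2.7, amplitude_contrast=0.1,
                     defocus_u=12000.0, defocus_v=10000.0, astig_angle=30.0)
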