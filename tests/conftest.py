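import numpy as np
import pytest

from ecogloc.ct_io import CTVolume
from ecogloc.phantom import PhantomSpec, generate_phantom
from ecogloc.pipeline import extract_features, label_table_from_truth


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, dtype=np.float32)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return CTVolume(values=values, spacing=spacing, affine=affine, source_id="test")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_spec():
    # one 4-electrode strip plus a few distractors; small head keeps it fast
    return PhantomSpec(
        seed=1,
        strips=(4,),
        n_wires=2,
        n_stitches=3,
        n_screws=1,
        head_radius=40.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def small_phantom_pipeline(small_phantom):
    vol, truth = small_phantom
    labeling, table = extract_features(vol)
    labeled = label_table_from_truth(table, truth)
    return vol, truth, labeling, labeled


def rasterize_disc(radius_vox, half_thickness_vox, normal=None):
    """Voxel indices of a solid disc; optionally with an arbitrary normal."""
    r = int(np.ceil(radius_vox + half_thickness_vox)) + 2
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    pts = np.stack([g[0], g[1], g[2]], axis=-1).reshape(-1, 3).astype(float)
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ax = pts @ normal
    rad2 = np.einsum("ij,ij->i", pts, pts) - ax**2
    keep = (np.abs(ax) <= half_thickness_vox) & (rad2 <= radius_vox**2)
    return np.rint(pts[keep]).astype(int)
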