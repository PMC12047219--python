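import numpy as np
import pytest

from rseikit import Affine, BandStack, SceneParams, generate_scene, mask_clouds


def make_stack(shape=(4, 4), sensor="TM", valid=None, pixel_size=30.0, **bands):
    """BandStack from constant or array band values on a small grid."""
    for val in bands.values():
        if np.ndim(val) == 2:
            shape = np.shape(val)
            break
    arrays = {}
    for name, val in bands.items():
        arr = np.asarray(val, dtype=np.float64 if name != "qa" else np.int64)
        if arr.ndim == 0:
            arr = np.full(shape, arr)
        arrays[name] = arr
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return BandStack(
        bands=arrays,
        valid_mask=valid,
        transform=Affine(pixel_size, 0.0, 0.0, 0.0, -pixel_size, 0.0),
        crs_id="EPSG:32600",
        sensor=sensor,
    )


@pytest.fixture(scope="session")
def default_scene():
    """Default synthetic scene, clouds masked, ready for the index pipeline."""
    params = SceneParams(seed=7)
    stack, truth = generate_scene(params)
    return params, mask_clouds(stack), truth
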