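import numpy as np
import pandas as pd
import pytest

from crowdcell import SceneConfig, make_scene, render_channels

SPARSE = {c: 0.0 for c in ("endothelial", "immune", "other")}


def sparse_config(width=300, height=300, tumor=8e-5, astrocyte=5e-5,
                  neuron=0.0, noise_sd=0.02, min_spacing=40, **kw):
    densities = dict(SPARSE, tumor=tumor, astrocyte=astrocyte, neuron=neuron)
    return SceneConfig(width=width, height=height, densities=densities,
                       noise_sd=noise_sd, min_spacing=min_spacing, **kw)


@pytest.fixture(scope="session")
def small_scene():
    return make_scene(sparse_config(), seed=11)


@pytest.fixture(scope="session")
def small_stack(small_scene):
    return render_channels(small_scene)


def gt_points(n, seed, width=400, height=400, cell_class="tumor",
              margin=20.0):
    """Uniform ground-truth point table for crowd/aggregation tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "class": [cell_class] * n,
        "x": rng.uniform(margin, width - margin, n),
        "y": rng.uniform(margin, height - margin, n),
    })
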