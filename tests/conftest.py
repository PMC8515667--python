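import dataclasses

import numpy as np
import pytest

from sctgen.phantom import ArtifactSpec, PhantomSpec, generate_phantom, make_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact thorax phantom with its ROI labels."""
    spec = dataclasses.replace(PhantomSpec(), shape=(6, 48, 48), seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Three-volume aligned CT/CBCT/ROI cohort on disk (32x32 slices)."""
    root = tmp_path_factory.mktemp("ds")
    spec = dataclasses.replace(PhantomSpec(), shape=(4, 32, 32))
    manifest = make_dataset(
        root, 3, phantom_spec=spec, artifact_spec=ArtifactSpec(),
        seed=5, paired=True, train_fraction=0.7, overwrite=True,
    )
    manifest["_root"] = str(root)
    return manifest
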