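import numpy as np
import pytest

from radonglau.synthetic import SynthParams, generate_image


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def glaucoma_gray(default_params) -> np.ndarray:
    """One CLAHE-ready grayscale glaucomatous fundus image."""
    from radonglau.preprocessing import to_grayscale

    image, _ = generate_image(default_params, "glaucoma", draw_seed=3)
    return to_grayscale(image)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, default_params):
    """10 + 10 synthetic images on disk with their manifest."""
    from radonglau.synthetic import generate_dataset

    out = tmp_path_factory.mktemp("synth")
    manifest, manifest_path = generate_dataset(10, 10, default_params, out)
    return manifest, manifest_path, out
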