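import numpy as np
import pytest

import spectraplex as spx


@pytest.fixture(scope="session")
def prostate_cfg():
    return spx.assay_config("prostate_4plex")


@pytest.fixture(scope="session")
def stain_library():
    return {s.name: s for s in spx.default_stain_library()}


@pytest.fixture(scope="session")
def camera():
    return spx.CameraResponsivity.default()


@pytest.fixture(scope="session")
def prostate_slide(prostate_cfg):
    """256x256 prostate H&E + 4-plex virtual slide (round-trip workhorse)."""
    return spx.generate_tissue(
        prostate_cfg, spx.default_phenotypes("prostate_4plex"), 256, 256, seed=11
    )


@pytest.fixture(scope="session")
def prostate_captures(prostate_cfg, prostate_slide):
    return spx.render_assay(prostate_slide, prostate_cfg)


@pytest.fixture(scope="session")
def prostate_noisy_captures(prostate_cfg, prostate_slide):
    noise = spx.NoiseModel(shot_noise_scale=1e4, seed=12)
    return spx.render_assay(prostate_slide, prostate_cfg, noise=noise)


@pytest.fixture(scope="session")
def prostate_reference(prostate_cfg):
    """Reference matrix calibrated from simulated single-stain slides."""
    return spx.calibrate_assay(prostate_cfg, seed=13)


@pytest.fixture(scope="session")
def prostate_truth_matrix(prostate_cfg):
    return spx.truth_reference_matrix(prostate_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_stain_slide(stain_name, shape=(96, 96), abundance=1.0):
    """A uniform square deposit of one stain, ground truth retained."""
    amap = np.zeros(shape)
    amap[20:60, 20:60] = abundance
    return spx.VirtualSlide(
        width=shape[1],
        height=shape[0],
        abundance_maps={stain_name: amap},
        phenotype_table=[],
        seed=0,
    )
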