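import numpy as np
import pytest

from octaquant import pipeline, synth


@pytest.fixture
def noise_free_profile():
    """ICGA-like profile with all stochastic degradations disabled."""
    from dataclasses import replace

    return replace(
        synth.ICGA_PROFILE,
        speckle_shape=None,
        motion_line_rate=0.0,
        background_level=0.05,
    )


@pytest.fixture
def sharp_profile(noise_free_profile):
    """Noise-free profile with a negligible PSF (sub-pixel blur)."""
    from dataclasses import replace

    return replace(noise_free_profile, psf_fwhm_um=0.5, background_level=0.0)


def make_tree(segments):
    """VesselTree from raw segment tuples (parent, start, end, r_um, depth_um)."""
    return synth.VesselTree(
        segments=tuple(synth.VesselSegment(*s) for s in segments),
        growth_params=synth.GrowthParams(),
        seed=0,
    )


@pytest.fixture
def single_tube_tree():
    """One horizontal mid-depth vessel crossing the centre of the frame."""
    return make_tree([(None, (0.2, 0.5), (0.8, 0.5), 30.0, 150.0)])


@pytest.fixture
def table1_columns():
    """The bundled reference dataset as per-modality arrays, serial order."""
    from octaquant.io_formats import load_table1_fixture

    records = load_table1_fixture()
    cols = {}
    for modality in ("ICGA", "OMAG", "SSADA"):
        vals = [
            r.density_percent
            for r in records
            if r.modality == modality
        ]
        cols[modality] = np.array(vals)
    return cols


def unit_image(pixels, pixel_size_um=10.0, **kw):
    return pipeline.EnFaceImage(
        pixels=np.asarray(pixels, dtype=float), pixel_size_um=pixel_size_um, **kw
    )


def uint8_image(pixels, pixel_size_um=10.0, **kw):
    return pipeline.EnFaceImage(
        pixels=np.asarray(pixels, dtype=np.uint8), pixel_size_um=pixel_size_um, **kw
    )
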