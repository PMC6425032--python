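"""Shared synthetic fixtures (everything is generated at test time)."""

import numpy as np
import pytest

from phagokit import synthgen as sg
from phagokit import traction as tr


@pytest.fixture(scope="session")
def wave_scene():
    """Noiseless expanding/contracting wave with per-angle speeds in
    [-0.5, 1.5] um/min and linear speed-intensity coupling."""
    cfg = sg.SynthConfig(seed=3, image_shape=(256, 256))
    speeds = 0.5 + 1.0 * np.sin(np.deg2rad(np.arange(360)))
    radii = sg.expanding_wave_radii(8.0, speeds, n_frames=12,
                                    frame_interval_s=cfg.frame_interval_s)
    actin, membrane, truth = sg.gen_wave_movie(cfg, radii, intensity0=100.0,
                                               coupling_beta=0.1)
    return cfg, actin, membrane, truth


@pytest.fixture(scope="session")
def tfm_truth():
    """Balanced Gaussian traction dipole on a 64x64, 1.73 um grid over the
    study substrate (G = 1.5 kPa, nu = 0.5)."""
    cfg = sg.SynthConfig(seed=1)
    substrate = tr.ElasticSubstrate()
    patches = sg.gaussian_traction_dipole(center_um=(55.4, 55.4), separation_um=30,
                                          sigma_um=6.0, peak_pa=200.0)
    gt = sg.gen_tfm_field(cfg, patches, grid_shape=(64, 64), spacing_um=1.73,
                          substrate=substrate)
    return substrate, patches, gt


@pytest.fixture(scope="session")
def speckle_pair():
    """Bead speckle reference plus the same image warped by a uniform
    subpixel shift of (1.2, -0.7) px."""
    cfg = sg.SynthConfig(seed=5, pixel_size_um=0.054, image_shape=(512, 512))
    ref = sg.render_speckle(cfg, density_per_px2=0.04)
    warped = sg.warp_image(ref, shift_px=(1.2, -0.7))
    return cfg, ref, warped, (1.2, -0.7)
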