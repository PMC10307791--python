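import numpy as np
import pytest

from condquant import image, simulate


@pytest.fixture
def noiseless_config():
    """Unblurred, noise-free acquisition: estimators must be exact here."""
    def make(seed: int = 0, shape=(128, 128)):
        return simulate.SceneConfig(
            image_shape=shape, psf_sigma=0.0, noise=simulate.NoiseConfig(), seed=seed
        )
    return make


@pytest.fixture
def quantify_separation():
    """Run the full projection→segmentation→screening→SF pipeline."""
    def run(scene_result, smooth_sigma_px: float):
        proj = image.max_intensity_projection(scene_result.scene, 0)
        labels = image.segment_condensates(
            proj, image.SegmentationConfig(smooth_sigma_px=smooth_sigma_px)
        )
        bg = image.estimate_background(proj, labels > 0, min_pixels=10)
        cset = image.screen_condensates(labels, proj, bg)
        return image.separation_factor(proj, cset).separation_factor
    return run


@pytest.fixture
def quantify_enrichment():
    """Best-focus-slice enrichment pipeline on the client channel."""
    def run(scene_result, smooth_sigma_px: float = 0.0, bleedthrough_raw: float = 0.0):
        sc = scene_result.scene
        zi = image.best_focus_slice(sc, 0)
        cond = sc.stack(0)[zi]
        client = sc.stack(1)[zi]
        labels = image.segment_condensates(
            cond, image.SegmentationConfig(smooth_sigma_px=smooth_sigma_px)
        )
        bg = image.estimate_background(cond, labels > 0, min_pixels=10)
        cset = image.screen_condensates(labels, cond, bg)
        return image.client_enrichment(client, cset, bleedthrough_raw)
    return run


@pytest.fixture
def frap_time():
    """Standard acquisition grid: 5 pre-bleach + 40 post-bleach frames, 0.5 min."""
    return np.concatenate([np.arange(-5, 0) * 0.5, np.arange(40) * 0.5])
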