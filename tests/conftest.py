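import numpy as np
import pytest

from ihcmil.synthdata import SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """A 448x448 synthetic slide with tumor, immune and stroma regions."""
    spec = SyntheticSlideSpec(slide_id="fix448", width_px=448, height_px=448,
                              true_tps=0.5, true_cps_extra=0.2,
                              tumor_fraction=0.5, immune_fraction=0.25,
                              blank_fraction=0.0, seed=11)
    slide, gt = generate_slide(spec)
    return slide, gt, spec


@pytest.fixture(scope="session")
def textured_and_blank_tiles():
    """10 textured tissue tiles + 5 blank background tiles (224x224)."""
    from ihcmil.wsi_prep import tessellate

    tiles = []
    for seed in (3, 4):
        spec = SyntheticSlideSpec(slide_id=f"tex{seed}", width_px=1120,
                                  height_px=224, true_tps=0.3,
                                  tumor_fraction=0.6, immune_fraction=0.2,
                                  blank_fraction=0.0, seed=seed)
        slide, _ = generate_slide(spec)
        tiles.extend(tessellate(slide))
    textured = tiles[:10]
    rng = np.random.default_rng(9)
    blank = []
    from ihcmil.wsi_prep import Tile

    for i in range(5):
        px = np.clip(248 + rng.normal(0, 1, (224, 224, 3)), 0, 255).astype(np.uint8)
        blank.append(Tile(pixels=px, origin=(0, (10 + i) * 224), slide_id="blank"))
    return textured, blank
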