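import numpy as np
import pytest

from melapress import synth_data as sd


@pytest.fixture(scope="session")
def strain_scene():
    """Speckle pair under a homogeneous Exx = 0.02 stretch, mild noise."""
    spec = sd.SpecklePairSpec(
        displacement=sd.HomogeneousStrain(exx=0.02), noise_sd=0.02, seed=7
    )
    return sd.gen_speckle_pair(spec)


@pytest.fixture(scope="session")
def translation_scene():
    """Speckle pair under a rigid integer (3, 2) px shift, no noise."""
    spec = sd.SpecklePairSpec(displacement=sd.Translation(3, 2), seed=11)
    return sd.gen_speckle_pair(spec)


def zncc_bruteforce(ref, dfm, x, y, subset_size, search_radius):
    """Independent oracle: plain-loop ZNCC argmax over the search window.

    Returns (dx, dy, max_corr) over integer offsets.
    """
    h = subset_size // 2
    t = ref[y - h : y + h + 1, x - h : x + h + 1].astype(float)
    tz = t - t.mean()
    tss = (tz * tz).sum()
    best = (-np.inf, 0, 0)
    for dy in range(-search_radius, search_radius + 1):
        for dx in range(-search_radius, search_radius + 1):
            w = dfm[y - h + dy : y + h + 1 + dy, x - h + dx : x + h + 1 + dx].astype(float)
            wz = w - w.mean()
            denom = np.sqrt(tss * (wz * wz).sum())
            if denom <= 0:
                continue
            c = (tz * wz).sum() / denom
            if c > best[0]:
                best = (c, dx, dy)
    return best[1], best[2], best[0]
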