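import math

import numpy as np
import pytest

from renoperf import synthetic as syn


@pytest.fixture(scope="session")
def static_movie() -> syn.SpeckleMovie:
    """20 frames of static fully developed speckle (tau_c = inf, beta = 1)."""
    cfg = syn.SpeckleSimConfig(
        frame_height=128,
        frame_width=128,
        n_frames=20,
        tau_c_ms=math.inf,
        n_subframes=1,
        seed=11,
    )
    return syn.simulate_speckle_movie(cfg)


def brute_force_contrast(frame: np.ndarray, window: int = 5) -> np.ndarray:
    """Explicit per-pixel sliding-window K = std/mean (reflective padding)."""
    pad = window // 2
    padded = np.pad(np.asarray(frame, dtype=float), pad, mode="symmetric")
    out = np.empty(frame.shape, dtype=float)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            win = padded[i : i + window, j : j + window]
            out[i, j] = np.std(win, ddof=1) / np.mean(win)
    return out
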