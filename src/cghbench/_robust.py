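"""Small robust-scale helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["mad_scale"]

# consistency constant: MAD * 1.4826 estimates the sd under normality
MAD_CONSISTENCY = 1.4826


def mad_scale(x: np.ndarray) -> float:
    """Median absolute deviation of x, scaled to be sd-consistent."""
    x = np.asarray(x, dtype=float)
    return float(MAD_CONSISTENCY * np.median(np.abs(x - np.median(x))))
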