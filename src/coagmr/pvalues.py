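"""Shared small statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Smallest representable positive double; p-values are floored here so the
#: open-interval contract p in (0, 1] survives extreme z scores.
_TINY = np.nextafter(0.0, 1.0)


def two_sided_p(z):
    """Two-sided normal-tail p-value for a z score (scalar or array)."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, _TINY) if np.ndim(z) else max(float(p), _TINY)
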