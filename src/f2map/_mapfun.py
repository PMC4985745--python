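"""Kosambi mapping function and its inverse.

Kept in a leaf module so both the genotype-correction HMM and the map
builder can use it without an import cycle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kosambi", "kosambi_inverse", "MAX_RF"]

#: Largest recombination fraction accepted before the Kosambi transform
#: diverges; estimates at or above 0.5 are clamped here when a finite
#: distance is required.
MAX_RF = 0.499999


def kosambi(r):
    """Map a recombination fraction to Kosambi centimorgans.

    ``d = 25 * ln((1 + 2r) / (1 - 2r))``.  Accepts scalars or arrays with
    ``0 <= r < 0.5``; raises ``ValueError`` outside that domain.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Inverse of :func:`kosambi`: centimorgans back to a recombination fraction.

    ``r = tanh(d / 50) / 2``.  Accepts scalars or arrays with ``d >= 0``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r
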