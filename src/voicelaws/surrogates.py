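"""Shuffle null models.

The null model randomly permutes the instantaneous-energy series eps(t):
the marginal energy distribution is preserved exactly (the surrogate is the
same multiset of values) while every temporal correlation is destroyed,
yielding non-Gaussian white noise with a fat-tailed marginal.  A signal
whose law curves collapse across thresholds but whose surrogate's do not is
displaying genuine temporal structure, not an artifact of symbolization.
"""

from __future__ import annotations

import numpy as np

from .signal_io import AmplitudeSeries, EnergySeries

__all__ = ["shuffle_surrogate", "shuffle_amplitude"]


def shuffle_surrogate(
    e: EnergySeries, seed: int | np.random.Generator
) -> EnergySeries:
    """Uniform random permutation of the energy values (the null model)."""
    rng = np.random.default_rng(seed)
    return EnergySeries(
        rng.permutation(e.values), e.rate,
        source_label=f"{e.source_label}[shuffled]",
    )


def shuffle_amplitude(
    a: AmplitudeSeries, seed: int | np.random.Generator
) -> AmplitudeSeries:
    """Permutation in the amplitude domain (exploratory; not the null model —
    the null is defined on eps(t))."""
    rng = np.random.default_rng(seed)
    return AmplitudeSeries(
        rng.permutation(a.samples), a.rate,
        source_label=f"{a.source_label}[shuffled]",
    )
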