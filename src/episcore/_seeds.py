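"""Deterministic seed derivation.

A single root seed expands into independent per-component streams through
``numpy.random.SeedSequence`` with a fixed, registered spawn key per stream.
Adding a new stream name to the registry never perturbs existing streams.
"""

from __future__ import annotations

import numpy as np

# Registry of stream ids; append-only.
_STREAMS = {
    "reference_panel": 1,
    "cohort_traits": 2,
    "cohort_fractions": 3,
    "cohort_noise": 4,
    "effect_sites": 5,
    "survival": 6,
    "expression": 7,
    "permutation": 8,
    "moderation": 9,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Return the generator for a named stream under a root seed."""
    if stream not in _STREAMS:
        raise KeyError(f"unregistered random stream {stream!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.Generator(np.random.PCG64(ss))
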