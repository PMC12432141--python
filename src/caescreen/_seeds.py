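"""Deterministic seed substreams.

All randomness in the pipeline flows from one master seed. Each stage draws
from a named substream so that, e.g., changing the number of bootstrap
subsets never perturbs the simulated images.
"""

from __future__ import annotations

import numpy as np

# Fixed substream indices; order is part of the on-disk reproducibility
# contract and must not change.
_STREAMS = {"simulate": 0, "train": 1, "bootstrap": 2}


def substream(master_seed: int, name: str) -> np.random.SeedSequence:
    """Return the named child ``SeedSequence`` of ``master_seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown seed substream {name!r}")
    return np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[name],))


def child_seeds(seq: np.random.SeedSequence, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from ``seq``."""
    return [int(s) % (2**31) for s in seq.generate_state(n, dtype=np.uint64)]
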