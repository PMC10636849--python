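"""Named random substreams.

Every stochastic stage draws from its own independent generator derived from
the scenario seed and a stage name, so adding or reordering stages never
perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for stage ``name`` under ``seed``.

    The substream key is a CRC32 of the stage name, so the mapping is stable
    across sessions and platforms.
    """
    if not (0 <= int(seed) < 2**31):
        raise ValueError(f"seed must be in [0, 2^31): got {seed}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
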