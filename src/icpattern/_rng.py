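"""Named random substreams so each pipeline stage draws from its own stream."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    Streams for distinct names are statistically independent, and adding a new
    stage name never perturbs the draws of existing stages.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
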