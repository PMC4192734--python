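"""Named random substreams derived from one top-level seed.

Every stochastic stage draws from its own substream so that rerunning a
single stage with the same top-level seed reproduces its output exactly,
independent of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str, index: int | None = None) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of top-level ``seed``.

    ``index`` further splits a stream (e.g. one draw per genomic bin).
    """
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]
    if index is not None:
        key.append(int(index))
    return np.random.default_rng(np.random.SeedSequence(key))
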