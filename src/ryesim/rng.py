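"""Named random sub-streams.

Every stochastic component of a simulation run (historical drift, variety
sampling, QTL effects, meiosis, phenotypes, dosage sampling, Gibbs chains)
draws from its own named stream derived from one base seed.  Changing how
many numbers one component consumes therefore never shifts the draws of any
other component, which keeps runs replayable and comparisons across
scenarios paired.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key_ints(keys: tuple) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode()))
    return out


def substream(base_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``keys``.

    Keys may be strings (component names) or integers (cycle, replicate
    indices); they are hashed into the seed sequence entropy.
    """
    return np.random.default_rng(np.random.SeedSequence([int(base_seed)] + _key_ints(keys)))


def substream_seed(base_seed: int, *keys) -> int:
    """A 31-bit integer seed for consumers that need a plain seed (numba)."""
    return int(substream(base_seed, *keys).integers(2**31))
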