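"""Named, reproducible random substreams.

A single master seed is split into independent substreams ("game", "votes",
"policies", ...) so that each pipeline component is reproducible on its own:
re-running one component never perturbs the random draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of a master seed.

    The stream key is a CRC32 of the name, so streams are stable across
    processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None) to a ``numpy.random.Generator``."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
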