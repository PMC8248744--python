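"""Named random substreams derived from a single global seed.

Every stochastic stage draws from a :class:`numpy.random.Generator` obtained
through :func:`substream`, so that a run is fully reproducible from one
integer seed and stages cannot perturb each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(name: str) -> int:
    # stable 32-bit hash of the stream name (process-independent, unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return a generator for the substream identified by ``names``.

    Parameters
    ----------
    seed
        The single global seed of the run.
    names
        Stage / replicate identifiers, e.g. ``("simulate", "pair", 3)``.
        Strings are hashed with CRC32; integers are used as-is.
    """
    spawn_key = tuple(_key(n) if isinstance(n, str) else int(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))
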