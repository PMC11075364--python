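"""Deterministic random-number streams.

One user-facing seed drives the whole pipeline; stages and items derive
independent substreams from (seed, named keys) so re-running any stage in
isolation reproduces its draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
    return int(key) & 0x7FFFFFFF


def derive_seed(seed: int, *keys) -> int:
    """A 31-bit seed deterministically derived from (seed, keys)."""
    ss = np.random.SeedSequence([int(seed)] + [_key_to_int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def derive_rng(seed, *keys) -> np.random.Generator:
    """A Generator from an int seed plus optional named subkeys.

    Passing an existing Generator returns it unchanged (keys ignored), so
    functions can accept either a seed or a live stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    ss = np.random.SeedSequence([int(seed)] + [_key_to_int(k) for k in keys])
    return np.random.default_rng(ss)
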