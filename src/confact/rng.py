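"""Hierarchical seed derivation.

All randomness in a run flows from a single master seed. Each stage derives
its own child seed from the master seed plus a stage name (and optional
indices), so any stage can be re-run in isolation and reproduce its stream.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, *names: object) -> int:
    """Derive a deterministic child seed from ``master`` and a name path.

    The derivation is a CRC32 fold of the stage names mixed into a
    ``numpy.random.SeedSequence``; it is stable across platforms and Python
    processes (unlike ``hash``). The result lies in ``[0, 2**31 - 2]`` so it
    is accepted by every downstream library (sklearn, numpy legacy).
    """
    tag = zlib.crc32("/".join(str(n) for n in names).encode("utf-8"))
    ss = np.random.SeedSequence([int(master) % _MOD, tag])
    return int(ss.generate_state(1)[0] % _MOD)


def derive_rng(master: int, *names: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *names))
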