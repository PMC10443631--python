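"""Shared helpers: seeding, hashing, logging."""

from __future__ import annotations

import hashlib
import logging
import zlib

import numpy as np

logger = logging.getLogger("ossa")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive an independent, stable sub-seed for a named pipeline stage.

    The stage name is hashed (CRC32) into the spawn key of a
    ``numpy.random.SeedSequence`` so that toggling one stage never perturbs
    the random stream of another.  The result is always < 2**31.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
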