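"""Stage-keyed seed derivation.

A single run seed fans out to per-stage substreams keyed by the stage
name (CRC32 of the name mixed into a SeedSequence), so adding a stage
never perturbs the random streams of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed (< 2^31) for a named stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf8"))])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
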