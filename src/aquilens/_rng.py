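"""Seed handling.

A single master seed fans out to per-stage seeds through a counter-based
``SeedSequence`` derivation, so that changing one stage's seed usage cannot
perturb another stage's random stream.
"""

from __future__ import annotations

import numpy as np

# stable stage indices for the counter-based fan-out
STAGE_IDS = {
    "generate": 0,
    "split": 1,
    "network": 2,
    "tune": 3,
    "head": 4,
    "ensemble": 5,
    "explain": 6,
}


def stage_seed(master_seed: int, stage: str | int) -> int:
    """Derive a 31-bit stage seed from the master seed and a stage name/index."""
    idx = STAGE_IDS[stage] if isinstance(stage, str) else int(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
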