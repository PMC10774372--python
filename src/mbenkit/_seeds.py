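"""Deterministic seed derivation for pipeline stages.

A single global seed spawns one sub-seed per named stage so that toggling
one stage on or off never perturbs the random stream of another.
"""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % _MOD
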