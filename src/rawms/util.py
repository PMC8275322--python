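"""Seed plumbing shared by every stochastic stage.

All randomness in the pipeline flows from one master seed; each stage asks
for a child seed under a descriptive label so that changing one stage never
perturbs another, and the same (master, label) pair always yields the same
child seed.
"""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage seed deterministically from a master seed and a label.

    Returns a nonnegative int below 2**31, suitable for numpy and sklearn
    ``random_state`` arguments.
    """
    payload = f"{int(master_seed)}:{label}".encode()
    return zlib.crc32(payload) & 0x7FFFFFFF
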