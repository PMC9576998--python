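"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(*parts: int) -> int:
    """Deterministically mix integer parts into one 31-bit seed.

    Used wherever a reproducible child seed is needed (per matrix cell, per
    repetition, per subject) so that independent draws never share a stream.
    """
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
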