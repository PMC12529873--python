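"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def derive_seed(*parts: int) -> int:
    """Deterministically derive a 31-bit child seed from integer parts.

    Built on :class:`numpy.random.SeedSequence` so that nearby inputs give
    statistically independent streams.
    """
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
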