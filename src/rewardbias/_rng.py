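"""Seed-derivation helper shared by cohort construction and the pipeline."""

from __future__ import annotations

import numpy as np


def seed31(ss: np.random.SeedSequence) -> int:
    """Derive a 31-bit integer seed from a SeedSequence child stream."""
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> np.uint64(33))
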