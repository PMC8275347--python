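"""Seed fan-out: one user-facing seed, named independent substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage, derived deterministically from ``seed``.

    Distinct stage names yield statistically independent streams, so
    e.g. re-running only the mixing stage does not perturb simulation
    draws.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
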