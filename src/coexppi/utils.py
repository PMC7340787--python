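"""Shared helpers: errors and seeded random streams."""

from __future__ import annotations

import numpy as np


class CoexppiError(Exception):
    """Base class for all package errors."""


class ConfigError(CoexppiError):
    """Invalid configuration (CLI exit code 2)."""


class StageError(CoexppiError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of a master seed.

    All randomness in the package flows from one integer seed; distinct
    stages draw from distinct streams so that adding draws to one stage
    never perturbs another.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))
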