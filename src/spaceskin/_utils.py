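"""Shared helpers: seed streaming and validation errors."""

from __future__ import annotations

import numpy as np


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


class SeedStream:
    """Deterministic per-stage sub-seed dispenser.

    One global seed streams stage seeds via a counter so that each pipeline
    stage gets an independent, reproducible ``numpy.random.Generator``.
    """

    def __init__(self, seed: int):
        if not (0 <= int(seed) < 2**31):
            raise ValidationError(f"seed must be in [0, 2^31), got {seed}")
        self.seed = int(seed)
        self._counter = 0

    def spawn(self) -> np.random.Generator:
        rng = np.random.default_rng([self.seed, self._counter])
        self._counter += 1
        return rng

    def child_seed(self) -> int:
        """An integer sub-seed (for libraries that take ints, e.g. UMAP)."""
        rng = self.spawn()
        return int(rng.integers(0, 2**31 - 1))


def check_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1]).all():
        raise ValidationError(f"labels must be binary 0/1, got values {uniq}")
    if uniq.size < 2:
        raise ValidationError("both classes must be present")
    return y.astype(int)
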