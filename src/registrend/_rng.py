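"""Named RNG substreams.

A single integer seed fans out to independent, order-insensitive substreams
keyed by string labels, so e.g. changing trend-analysis settings never
perturbs imputation draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    Deterministic in (seed, labels); distinct labels give statistically
    independent streams via :class:`numpy.random.SeedSequence`.
    """
    key = "/".join(str(x) for x in labels)
    digest = zlib.crc32(key.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))
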