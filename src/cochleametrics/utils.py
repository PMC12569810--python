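"""Shared helpers: seeded RNG fan-out and provenance records."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np


def rng_from(seed: int | np.random.Generator | None, *key: str) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and an optional string key.

    A single pipeline seed is fanned out into independent per-stage substreams
    by hashing the key into the SeedSequence spawn chain, so stages can be rerun
    in isolation without perturbing each other's streams.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if key:
        digest = hashlib.sha256("/".join(key).encode()).digest()
        extra = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
        ss = np.random.SeedSequence([0 if seed is None else int(seed), *extra])
    else:
        ss = np.random.SeedSequence(None if seed is None else int(seed))
    return np.random.default_rng(ss)


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(seed: int | None, config: Any = None, **extra: Any) -> dict:
    from cochleametrics import __version__

    rec = {"tool": "cochleametrics", "version": __version__, "seed": seed}
    if config is not None:
        rec["config_hash"] = config_hash(config)
    rec.update(extra)
    return rec
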