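"""Named, reproducible random streams.

A single root seed spawns independent streams per model component (cohort
synthesis, time-varying factors, usage draws, onset draws, mortality,
parameter sampling, calibration restarts).  Because each stream is keyed by
name, changing how one component consumes randomness never perturbs the
draws of another — a prerequisite for the common-random-number comparisons
used in calibration and scenario contrasts.
"""

from __future__ import annotations

import numpy as np

_STREAM_IDS = {
    "cohort": 0,
    "factors": 1,
    "usage": 2,
    "onset": 3,
    "mortality": 4,
    "params": 5,
    "calibration": 6,
    "targets": 7,
    "ensemble": 8,
}


def stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Generator for the named stream of a root seed.

    ``extra`` integers sub-key the stream (e.g. per replicate or iteration).
    """
    if name not in _STREAM_IDS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAM_IDS)}")
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(_STREAM_IDS[name], *map(int, extra)))
    return np.random.default_rng(ss)
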