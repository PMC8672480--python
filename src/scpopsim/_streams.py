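"""Named random substreams derived from one master seed.

Every stochastic stage of the simulator draws from its own generator, keyed
by (master_seed, stage name). Changing the number of genes or individuals
therefore perturbs only the streams that consume more draws, and two runs
that share a master seed but differ in, say, single-cell parameters still
produce identical gene-level ground truth.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: the integer key, not the dict order, defines each stream.
_STREAMS = {
    "annotation": 0,
    "genotypes": 1,
    "eqtl": 2,
    "means": 3,
    "variances": 4,
    "individuals": 5,
    "de": 6,
    "design": 7,
    "batch": 8,
    "lib": 9,
    "counts": 10,
    "dropout": 11,
}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return the generator for stage ``name`` under ``master_seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=(int(master_seed), _STREAMS[name]))
    return np.random.default_rng(ss)
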