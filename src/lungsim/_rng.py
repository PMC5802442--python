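"""Per-person named random substreams.

Every stochastic ingredient of a simulated person (smoking history, other-cause
death, tumor process, survival quantile, screen detection) is drawn from its own
generator, derived deterministically from ``(master_seed, person_id, stream)``.
Scenario comparison under common random numbers relies on this: the screening
scenario may consume extra detection draws without perturbing any other stream.
"""

from __future__ import annotations

import numpy as np

#: Registered substream names, in draw-order convention.
STREAMS = {
    "build": 0,        # demographics + smoking history + adherence uniform
    "other_cause": 1,  # competing (non-lung-cancer) mortality
    "tumor": 2,        # onset, histology, preclinical progression
    "survival": 3,     # post-diagnosis survival quantile
    "detection": 4,    # per-exam screen detection uniforms
}


def substream(master_seed: int, person_id: int, name: str) -> np.random.Generator:
    """Return the named, reproducible generator for one person.

    Independence across (person, stream) pairs comes from ``SeedSequence``
    spawn keys, which are designed for exactly this tree-structured use.
    """
    code = STREAMS[name]
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(person_id), code))
    return np.random.default_rng(ss)


def replication_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit replication seeds from one master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]
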