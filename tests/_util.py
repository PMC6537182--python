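"""Shared helpers for the test suite."""

import numpy as np

from whogem.containers import QMatrix


def dirichlet_q(n: int, k: int, seed: int = 0) -> QMatrix:
    rng = np.random.default_rng(seed)
    return QMatrix([f"s{i}" for i in range(n)], rng.dirichlet(np.ones(k), n))
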