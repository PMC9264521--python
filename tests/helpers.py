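"""Small sequence-construction helpers shared across tests."""

import numpy as np

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate`` to a different base."""
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def substitute(seq: str, positions, base_map=None) -> str:
    """Substitute given positions deterministically to a different base."""
    rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = (base_map or rotate)[out[p]]
    return "".join(out)
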