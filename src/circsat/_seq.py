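"""Small shared sequence utilities."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return "".join(rng.choice(list(BASES), size=n))


def child_rng(rng_or_seed, *salt: int) -> np.random.Generator:
    """Derive an independent generator from a seed (or generator) plus salt ints.

    Keeps every derived seed below 2**31 so seeds remain portable.
    """
    if isinstance(rng_or_seed, np.random.Generator):
        base = int(rng_or_seed.integers(0, 2**31 - 1))
    else:
        base = int(rng_or_seed) % (2**31 - 1)
    mixed = base
    for s in salt:
        mixed = (mixed * 1_000_003 + int(s) + 1) % (2**31 - 1)
    return np.random.default_rng(mixed)


def validate_dna(seq: str, *, allow_n: bool = True, what: str = "sequence") -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
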