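"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def roman(n: int) -> str:
    """Roman numeral for small positive integers (intron labels)."""
    if not 0 < n < 40:
        raise ValueError(f"roman numeral out of supported range: {n}")
    out = []
    for value, sym in ((10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")):
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def write_fasta(path, records, width: int = 70) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
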