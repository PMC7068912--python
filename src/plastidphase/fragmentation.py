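"""Cutting a genome into overlapping windows of length L at step R.

The defaults L=603, R=11 give roughly 10^4 windows per plastome, each a bit
shorter than a typical gene.  L must be odd and divisible by 3 so that the
window has an integer central nucleotide and tiles into whole triplets; R
must not be divisible by 3 so that consecutive windows sample all three
reading-frame offsets.  Extraction is linear: the last window is the last
full-length one, giving exactly floor((N-L)/R) + 1 fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeRecord

DEFAULT_FRAGMENT_LENGTH = 603
DEFAULT_STEP = 11


class ParameterError(ValueError):
    """Fragment length / step violate the arithmetic constraints."""


def validate_parameters(L: int, R: int) -> None:
    if L <= 0 or R <= 0:
        raise ParameterError(f"L and R must be positive (got L={L}, R={R})")
    if L % 2 == 0:
        raise ParameterError(f"fragment length L={L} must be odd")
    if L % 3 != 0:
        raise ParameterError(f"fragment length L={L} must be divisible by 3")
    if R % 3 == 0:
        raise ParameterError(f"step R={R} must not be divisible by 3")


@dataclass(frozen=True)
class Fragment:
    """One length-L window; ``start`` and ``center`` are 1-based."""

    genome_id: str
    index: int
    start: int
    sequence: str

    @property
    def center(self) -> int:
        return self.start + (len(self.sequence) - 1) // 2

    @property
    def length(self) -> int:
        return len(self.sequence)


def fragment_count(n: int, L: int, R: int) -> int:
    """Number of full windows of length L at step R in a sequence of length n."""
    if L > n:
        raise ValueError(f"fragment length L={L} exceeds sequence length {n}")
    return (n - L) // R + 1


def fragmentize(
    genome: GenomeRecord,
    L: int = DEFAULT_FRAGMENT_LENGTH,
    R: int = DEFAULT_STEP,
) -> list[Fragment]:
    """Cut ``genome`` into overlapping fragments, in genome order.

    Fragment ``i`` covers positions ``1 + i*R .. i*R + L`` (1-based,
    inclusive); no window wraps past the end of the sequence.
    """
    validate_parameters(L, R)
    n = genome.length
    count = fragment_count(n, L, R)  # raises if L > n
    seq = genome.sequence
    return [
        Fragment(genome.id, i, 1 + i * R, seq[i * R : i * R + L])
        for i in range(count)
    ]
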