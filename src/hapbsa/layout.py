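"""Genome layout: ordered chromosomes and sliding-window grids.

Coordinates follow the two standard conventions used side by side in genomics
tooling: sites and windows are 1-based inclusive internally (VCF-style), and
intervals are exported 0-based half-open (BED-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenomeLayout", "WindowParams"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered (chromosome, length) list defining window placement.

    Chromosomes must be ordered by decreasing length; this is the order in
    which they are concatenated when the genome is circularized for the
    permutation test.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        lengths = [l for _, l in self.chromosomes]
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        if lengths != sorted(lengths, reverse=True):
            raise ValueError("chromosomes must be ordered by decreasing length")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @classmethod
    def from_lengths(cls, lengths: list[int], prefix: str = "chr") -> "GenomeLayout":
        """Build a layout named ``chr1..chrN`` from bp lengths (longest first)."""
        ordered = sorted(lengths, reverse=True)
        return cls(tuple((f"{prefix}{i + 1}", int(l)) for i, l in enumerate(ordered)))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return l
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def window_starts(self, chrom: str, size: int, step: int) -> np.ndarray:
        """1-based start positions of constant-width windows on ``chrom``.

        Windows begin at position 1 and advance by ``step``; a trailing window
        that would extend past the chromosome end is dropped, not truncated,
        so every window has identical width.
        """
        length = self.length(chrom)
        if size > length:
            return np.empty(0, dtype=np.int64)
        n = (length - size) // step + 1
        return 1 + step * np.arange(n, dtype=np.int64)


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window settings for the DNA allele-frequency scan.

    Defaults: 75 kb windows advanced in 5 kb steps, with a window kept only
    if it contains at least 38 informative sites.
    """

    size: int = 75_000
    step: int = 5_000
    min_sites: int = 38

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
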