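"""Genomic containers: intervals, peak sets, chromosome sizes, signal tracks.

Every coordinate in the package is 0-based half-open (BED convention):
an interval ``[start, end)`` covers bases ``start .. end-1`` and two
intervals that merely touch at a boundary share no base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ChromSizes:
    """Chromosome name -> length (bp) lookup."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if int(length) <= 0:
                raise ValidationError(
                    f"chromosome {chrom!r} has non-positive length {length}"
                )
            self.sizes[chrom] = int(length)

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __len__(self) -> int:
        return len(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def total(self) -> int:
        return sum(self.sizes.values())


@dataclass
class PeakSet:
    """A labelled collection of genomic intervals (a BED peak set).

    Intervals may overlap each other; arrays are parallel and intervals are
    not required to be sorted (operations sort internally as needed).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValidationError("peak set arrays have unequal lengths")
        bad = np.where((self.starts < 0) | (self.starts >= self.ends))[0]
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"invalid interval {self.chroms[i]}:"
                f"{self.starts[i]}-{self.ends[i]} (need 0 <= start < end)"
            )

    @classmethod
    def from_intervals(cls, intervals: list[GenomicInterval] | list[tuple],
                       label: str = "") -> "PeakSet":
        chroms, starts, ends = [], [], []
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chroms.append(iv.chrom); starts.append(iv.start); ends.append(iv.end)
            else:
                c, s, e = iv
                chroms.append(c); starts.append(int(s)); ends.append(int(e))
        return cls(np.array(chroms, dtype=object),
                   np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64), label=label)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield GenomicInterval(str(c), int(s), int(e))

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints (floor for even lengths)."""
        return (self.starts + self.ends) // 2

    def validate_against(self, sizes: ChromSizes) -> None:
        for i, chrom in enumerate(self.chroms):
            if chrom not in sizes:
                raise ValidationError(
                    f"interval on unknown chromosome {chrom!r}"
                )
            if self.ends[i] > sizes[chrom]:
                raise ValidationError(
                    f"interval {chrom}:{self.starts[i]}-{self.ends[i]} "
                    f"extends beyond chromosome end {sizes[chrom]}"
                )

    def sorted(self) -> "PeakSet":
        order = np.lexsort((self.ends, self.starts, self.chroms.astype(str)))
        return PeakSet(self.chroms[order], self.starts[order],
                       self.ends[order], label=self.label)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Dict chrom -> (starts, ends), each sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(set(self.chroms.astype(str))):
            sel = self.chroms.astype(str) == chrom
            s, e = self.starts[sel], self.ends[sel]
            order = np.argsort(s, kind="stable")
            out[chrom] = (s[order], e[order])
        return out


@dataclass
class SignalTrack:
    """Piecewise-constant genomic signal (the in-memory form of a bedGraph).

    ``data`` maps chromosome -> (starts, ends, values) with intervals sorted
    and non-overlapping; bases not covered by any interval carry signal 0.
    A cached prefix integral supports O(log n) evaluation of
    ``integral(chrom, x) = \\int_{-inf}^{x} signal``.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in self.data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if ((s < 0) | (s >= e)).any():
                i = int(np.where((s < 0) | (s >= e))[0][0])
                raise ValidationError(
                    f"invalid track interval {chrom}:{s[i]}-{e[i]}"
                )
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                i = int(np.where(s[1:] < e[:-1])[0][0])
                raise ValidationError(
                    f"overlapping track intervals on {chrom} near "
                    f"{s[i + 1]} (bedGraph intervals must not overlap)"
                )
            clean[chrom] = (s, e, v)
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(v * (e - s))]
            )
        self.data = clean

    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    def integral(self, chrom: str, x) -> np.ndarray:
        """Integral of the signal over (-inf, x] for scalar or array x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if chrom not in self.data:
            return np.zeros_like(x)
        s, e, v = self.data[chrom]
        idx = np.searchsorted(s, x, side="right") - 1
        out = np.zeros_like(x)
        inside = idx >= 0
        ii = idx[inside]
        partial = np.clip(x[inside] - s[ii], 0, (e - s)[ii])
        out[inside] = self._cum[chrom][ii] + v[ii] * partial
        return out

    @property
    def total_mass(self) -> float:
        return float(sum(c[-1] for c in self._cum.values()))

    def to_lines(self):
        """Yield (chrom, start, end, value) in sorted order."""
        for chrom in self.chromosomes():
            s, e, v = self.data[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])
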