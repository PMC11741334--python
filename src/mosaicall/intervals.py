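"""Strand-agnostic genomic interval sets with merge / pad / subtract.

Intervals are 0-based half-open (BED convention) and kept per chromosome as
sorted, merged, disjoint numpy arrays, so set algebra is a linear sweep.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class IntervalSet:
    """A merged, disjoint set of genomic intervals (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end < start:
                raise ValueError(f"interval end < start: {chrom}:{start}-{end}")
            if end > start:
                by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            arr = np.asarray(ivs, dtype=np.int64)
            self._data[chrom] = _merge(arr[:, 0], arr[:, 1])

    @classmethod
    def _from_arrays(cls, data: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        obj = cls()
        obj._data = {c: (s, e) for c, (s, e) in data.items() if s.size}
        return obj

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    @property
    def total_bases(self) -> int:
        return int(sum((e - s).sum() for s, e in self._data.values()))

    def __len__(self) -> int:
        return sum(s.size for s, _ in self._data.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            s, e = self._data[chrom]
            for a, b in zip(s.tolist(), e.tolist()):
                yield chrom, a, b

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        if chrom not in self._data:
            return False
        s, e = self._data[chrom]
        i = np.searchsorted(s, pos, side="right") - 1
        return i >= 0 and pos < e[i]

    def pad(self, padding: int) -> "IntervalSet":
        """Extend every interval by ``padding`` bases on both sides and re-merge."""
        if padding < 0:
            raise ValueError("padding must be non-negative")
        out = {}
        for chrom, (s, e) in self._data.items():
            out[chrom] = _merge(np.maximum(s - padding, 0), e + padding)
        return IntervalSet._from_arrays(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self._data) | set(other._data):
            s1, e1 = self._data.get(chrom, (np.empty(0, np.int64),) * 2)
            s2, e2 = other._data.get(chrom, (np.empty(0, np.int64),) * 2)
            out[chrom] = _merge(np.concatenate([s1, s2]), np.concatenate([e1, e2]))
        return IntervalSet._from_arrays(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Remove every base of ``other`` from this set."""
        out = {}
        for chrom, (s, e) in self._data.items():
            if chrom not in other._data:
                out[chrom] = (s, e)
                continue
            os, oe = other._data[chrom]
            res_s, res_e = [], []
            j = 0
            for a, b in zip(s.tolist(), e.tolist()):
                cur = a
                while j < os.size and oe[j] <= cur:
                    j += 1
                k = j
                while k < os.size and os[k] < b:
                    if os[k] > cur:
                        res_s.append(cur)
                        res_e.append(int(os[k]))
                    cur = max(cur, int(oe[k]))
                    if cur >= b:
                        break
                    k += 1
                if cur < b:
                    res_s.append(cur)
                    res_e.append(b)
            out[chrom] = (
                np.asarray(res_s, dtype=np.int64),
                np.asarray(res_e, dtype=np.int64),
            )
        return IntervalSet._from_arrays(out)

    def restrict_chromosomes(self, keep: Iterable[str]) -> "IntervalSet":
        keep = set(keep)
        return IntervalSet._from_arrays(
            {c: v for c, v in self._data.items() if c in keep}
        )

    def positions(self, chrom: str) -> np.ndarray:
        """All covered positions on a chromosome (0-based)."""
        if chrom not in self._data:
            return np.empty(0, dtype=np.int64)
        s, e = self._data[chrom]
        return np.concatenate([np.arange(a, b) for a, b in zip(s, e)])

    # --- BED I/O ------------------------------------------------------------

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                ivs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")
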