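"""Genomic interval containers, BED/chrom.sizes I/O, and genome-context builders.

Coordinates are 0-based half-open throughout, matching BED. An annotation is a
set of disjoint intervals on each chromosome, with any two intervals separated
by at least one uncovered base; overlapping or bookended input records are
merged on load so this invariant always holds. A genome context assigns every
position a class label from a finite set; it is stored run-length encoded as
segment start positions plus labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "Annotation",
    "GenomeContext",
    "read_chrom_sizes",
    "read_annotation",
    "read_context",
    "build_relative_context",
    "build_gc_context",
]


class ValidationError(ValueError):
    """Raised when an input file or interval set violates a structural invariant."""


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping or bookended (end == next begin) sorted intervals."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out_b = [arr[0, 0]]
    out_e = [arr[0, 1]]
    for b, e in arr[1:]:
        if b <= out_e[-1]:  # overlap or bookend: extend
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_b.append(b)
            out_e.append(e)
    return np.column_stack([out_b, out_e]).astype(np.int64)


@dataclass
class Annotation:
    """Per-chromosome sorted, disjoint, >=1-base-separated half-open intervals.

    Parameters
    ----------
    intervals
        Mapping chromosome name -> (n, 2) int array of (begin, end) pairs.
    lengths
        Mapping chromosome name -> chromosome length in bp. Every chromosome
        with intervals must have a known length; chromosomes may have a length
        but no intervals.
    """

    intervals: dict[str, np.ndarray]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if chrom not in self.lengths:
                raise ValidationError(f"no chromosome length known for {chrom!r}")
            L = self.lengths[chrom]
            if len(arr):
                if np.any(arr[:, 0] >= arr[:, 1]):
                    k = int(np.argmax(arr[:, 0] >= arr[:, 1]))
                    raise ValidationError(
                        f"{chrom}: empty or inverted interval {tuple(arr[k])}"
                    )
                if arr[:, 0].min() < 0 or arr[:, 1].max() > L:
                    raise ValidationError(
                        f"{chrom}: interval outside [0, {L})"
                    )
                order = np.argsort(arr[:, 0], kind="stable")
                arr = _merge_sorted(arr[order])
            clean[chrom] = arr
        self.intervals = clean

    @property
    def chroms(self) -> list[str]:
        return sorted(self.intervals)

    def n_intervals(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.intervals.get(chrom, ()))
        return sum(len(v) for v in self.intervals.values())

    def covered_bases(self, chrom: str | None = None) -> int:
        if chrom is not None:
            arr = self.intervals.get(chrom)
            return int((arr[:, 1] - arr[:, 0]).sum()) if arr is not None and len(arr) else 0
        return sum(self.covered_bases(c) for c in self.intervals)

    def get(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for b, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{b}\t{e}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        if set(self.intervals) != set(other.intervals):
            return False
        return all(
            np.array_equal(self.intervals[c], other.intervals[c]) for c in self.intervals
        ) and self.lengths == other.lengths


@dataclass
class GenomeContext:
    """Run-length encoded mapping of every genome position to a class label.

    ``starts[chrom]`` holds segment start positions (first entry always 0) and
    ``labels[chrom]`` the label of each segment; segments tile [0, L) exactly
    and adjacent segments always carry distinct labels (same-label neighbours
    are merged on construction). The number of class boundaries ``c`` is the
    number of positions whose label differs from the previous position.
    """

    starts: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, L in self.lengths.items():
            if L <= 0:
                raise ValidationError(f"{chrom}: non-positive length {L}")
            if chrom not in self.starts:
                raise ValidationError(f"{chrom}: no context segments for chromosome")
        for chrom in self.starts:
            st = np.asarray(self.starts[chrom], dtype=np.int64)
            lab = list(self.labels[chrom])
            if len(st) != len(lab) or len(st) == 0 or st[0] != 0:
                raise ValidationError(f"{chrom}: malformed context segments")
            if np.any(np.diff(st) <= 0) or st[-1] >= self.lengths[chrom]:
                raise ValidationError(f"{chrom}: context segments do not tile [0, L)")
            # merge adjacent same-label segments
            keep = [0] + [i for i in range(1, len(lab)) if lab[i] != lab[i - 1]]
            self.starts[chrom] = st[keep]
            self.labels[chrom] = [lab[i] for i in keep]

    @classmethod
    def single_class(
        cls, lengths: Mapping[str, int], label: str = "background"
    ) -> "GenomeContext":
        return cls(
            starts={c: np.array([0], dtype=np.int64) for c in lengths},
            labels={c: [label] for c in lengths},
            lengths=dict(lengths),
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.lengths)

    def label_set(self) -> set[str]:
        out: set[str] = set()
        for lab in self.labels.values():
            out.update(lab)
        return out

    def n_boundaries(self, chrom: str | None = None) -> int:
        """Number of class boundaries c (positions whose label differs from the previous)."""
        if chrom is not None:
            return len(self.starts[chrom]) - 1
        return sum(len(s) - 1 for s in self.starts.values())

    def first_label(self, chrom: str) -> str:
        return self.labels[chrom][0]

    def label_at(self, chrom: str, pos: int) -> str:
        if not 0 <= pos < self.lengths[chrom]:
            raise IndexError(f"position {pos} outside [0, {self.lengths[chrom]})")
        i = int(np.searchsorted(self.starts[chrom], pos, side="right")) - 1
        return self.labels[chrom][i]

    def runs(self, chrom: str) -> Iterator[tuple[int, int, str]]:
        """Yield (start, end, label) for each segment on ``chrom``."""
        st = self.starts[chrom]
        lab = self.labels[chrom]
        ends = np.append(st[1:], self.lengths[chrom])
        for s, e, l in zip(st, ends, lab):
            yield int(s), int(e), l

    def runs_between(self, chrom: str, start: int, end: int) -> list[tuple[int, str]]:
        """Maximal same-class runs covering [start, end) as (length, label) pairs."""
        if start == end:
            return []
        if not 0 <= start < end <= self.lengths[chrom]:
            raise IndexError(f"[{start}, {end}) outside [0, {self.lengths[chrom]})")
        st = self.starts[chrom]
        lab = self.labels[chrom]
        i = int(np.searchsorted(st, start, side="right")) - 1
        j = int(np.searchsorted(st, end, side="left"))
        ends = np.append(st[1:], self.lengths[chrom])
        out = []
        for k in range(i, j):
            s = max(int(st[k]), start)
            e = min(int(ends[k]), end)
            if e > s:
                out.append((e - s, lab[k]))
        return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected 'name<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: bad length {parts[1]!r}") from exc
    return sizes


def _parse_bed_lines(path: str | Path, n_cols: int) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < n_cols:
                raise ValidationError(
                    f"{path}:{ln}: expected at least {n_cols} columns, got {len(parts)}"
                )
            yield ln, parts


def read_annotation(path: str | Path, chrom_sizes: Mapping[str, int]) -> Annotation:
    """Read a BED3 file into an :class:`Annotation`.

    Records on chromosomes absent from ``chrom_sizes`` are dropped with a
    warning. Overlapping or bookended records are merged. A record with
    ``begin >= end``, ``begin < 0`` or ``end > L`` raises
    :class:`ValidationError` naming the offending line.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    dropped: set[str] = set()
    for ln, parts in _parse_bed_lines(path, 3):
        chrom = parts[0]
        try:
            b, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln}: non-integer coordinates") from exc
        if chrom not in chrom_sizes:
            dropped.add(chrom)
            continue
        L = chrom_sizes[chrom]
        if b < 0 or e > L:
            raise ValidationError(
                f"{path}:{ln}: interval [{b}, {e}) outside [0, {L}) on {chrom}"
            )
        if b >= e:
            raise ValidationError(f"{path}:{ln}: empty or inverted interval [{b}, {e})")
        per_chrom.setdefault(chrom, []).append((b, e))
    if dropped:
        logger.warning(
            "%s: dropped records on chromosomes absent from chrom.sizes: %s",
            path,
            ", ".join(sorted(dropped)),
        )
    intervals = {
        c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in per_chrom.items()
    }
    return Annotation(intervals=intervals, lengths=dict(chrom_sizes))


def read_context(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    default_label: str = "background",
) -> GenomeContext:
    """Read a BED4 file (4th column = class label) into a :class:`GenomeContext`.

    Positions not covered by any record receive ``default_label``. Overlapping
    records with conflicting labels raise :class:`ValidationError`; same-label
    overlaps are merged.
    """
    per_chrom: dict[str, list[tuple[int, int, str, int]]] = {}
    dropped: set[str] = set()
    for ln, parts in _parse_bed_lines(path, 4):
        chrom = parts[0]
        try:
            b, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln}: non-integer coordinates") from exc
        label = parts[3]
        if chrom not in chrom_sizes:
            dropped.add(chrom)
            continue
        L = chrom_sizes[chrom]
        if b < 0 or e > L:
            raise ValidationError(
                f"{path}:{ln}: interval [{b}, {e}) outside [0, {L}) on {chrom}"
            )
        if b >= e:
            raise ValidationError(f"{path}:{ln}: empty or inverted interval [{b}, {e})")
        per_chrom.setdefault(chrom, []).append((b, e, label, ln))
    if dropped:
        logger.warning(
            "%s: dropped context records on chromosomes absent from chrom.sizes: %s",
            path,
            ", ".join(sorted(dropped)),
        )
    starts: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    for chrom, L in chrom_sizes.items():
        recs = sorted(per_chrom.get(chrom, []))
        seg_starts: list[int] = []
        seg_labels: list[str] = []
        pos = 0
        for b, e, label, ln in recs:
            if b < pos:
                if seg_labels and seg_labels[-1] == label:
                    b = pos  # same-label overlap: absorb
                    if b >= e:
                        continue
                else:
                    raise ValidationError(
                        f"{path}:{ln}: record on {chrom} overlaps a previous record "
                        f"with a different label"
                    )
            if b > pos:
                seg_starts.append(pos)
                seg_labels.append(default_label)
            seg_starts.append(b)
            seg_labels.append(label)
            pos = e
        if pos < L:
            seg_starts.append(pos)
            seg_labels.append(default_label)
        starts[chrom] = np.array(seg_starts, dtype=np.int64)
        labels[chrom] = seg_labels
    return GenomeContext(starts=starts, labels=labels, lengths=dict(chrom_sizes))


def build_relative_context(
    R2: Annotation,
    chrom_sizes: Mapping[str, int],
    inside_label: str = "inside",
    outside_label: str = "outside",
) -> GenomeContext:
    """Two-class context labelling positions covered by ``R2`` as inside.

    Used for differential analysis of a reference R1 contained in a superset
    R2: within R1 the null model then uses chain parameters estimated from the
    query's behaviour inside R2.
    """
    starts: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    for chrom, L in chrom_sizes.items():
        arr = R2.get(chrom)
        seg_starts: list[int] = []
        seg_labels: list[str] = []
        pos = 0
        for b, e in arr:
            if b > pos:
                seg_starts.append(pos)
                seg_labels.append(outside_label)
            seg_starts.append(int(b))
            seg_labels.append(inside_label)
            pos = int(e)
        if pos < L or not seg_starts:
            seg_starts.append(pos)
            seg_labels.append(outside_label)
        starts[chrom] = np.array(seg_starts, dtype=np.int64)
        labels[chrom] = seg_labels
    return GenomeContext(starts=starts, labels=labels, lengths=dict(chrom_sizes))


def build_gc_context(
    fasta: str | Path,
    chrom_sizes: Mapping[str, int],
    window: int = 1000,
    n_bins: int = 5,
    gap_label: str = "gap",
) -> GenomeContext:
    """Discretize GC content in fixed windows into a genome context.

    The genome is tiled into ``window``-bp windows (the last may be short).
    Windows whose sequence is >=50% N get ``gap_label``; the rest are labelled
    ``gc<k>`` by GC fraction with equal-width right-closed bins on [0, 1],
    i.e. bin k covers (k/n, (k+1)/n] and GC = 0 falls in bin 0. N bases are
    excluded from the GC denominator.
    """
    from pyfaidx import Fasta

    if window < 1 or n_bins < 1:
        raise ValidationError("window and n_bins must be >= 1")
    fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    starts: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    for chrom in fa.keys():
        if chrom not in chrom_sizes:
            logger.warning("FASTA chromosome %s absent from chrom.sizes; skipped", chrom)
            continue
        seq = np.frombuffer(str(fa[chrom][:]).encode("ascii"), dtype=np.uint8)
        L = chrom_sizes[chrom]
        if len(seq) != L:
            raise ValidationError(
                f"{chrom}: FASTA length {len(seq)} != chrom.sizes length {L}"
            )
        is_gc = (seq == ord("G")) | (seq == ord("C")) | (seq == ord("g")) | (seq == ord("c"))
        is_n = (seq == ord("N")) | (seq == ord("n"))
        edges = np.arange(0, L, window)
        gc_w = np.add.reduceat(is_gc.astype(np.int64), edges)
        n_w = np.add.reduceat(is_n.astype(np.int64), edges)
        w_len = np.minimum(edges + window, L) - edges
        seg_labels: list[str] = []
        for gc, nn, wl in zip(gc_w, n_w, w_len):
            if nn * 2 >= wl:
                seg_labels.append(gap_label)
                continue
            denom = wl - nn
            frac = gc / denom if denom else 0.0
            k = int(np.ceil(frac * n_bins)) - 1
            k = min(max(k, 0), n_bins - 1)
            seg_labels.append(f"gc{k}")
        starts[chrom] = edges
        labels[chrom] = seg_labels
        lengths[chrom] = L
    if not lengths:
        raise ValidationError("no FASTA chromosome matched chrom.sizes")
    return GenomeContext(starts=starts, labels=labels, lengths=lengths)
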