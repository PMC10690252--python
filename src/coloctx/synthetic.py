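"""Synthetic annotation generator for benchmarks, calibration, and fixtures.

Emulates the standard simulation layout for colocalization benchmarks: a
single long chromosome carrying a fixed number of fixed-length intervals
placed uniformly at random among all valid non-colliding configurations
(pairwise separation of at least one base). Defaults are a scaled-down
version of the large-genome setting: L = 1e6, 500 intervals of 500 bp.
"""

from __future__ import annotations

import numpy as np

from .intervals import Annotation, ValidationError

__all__ = ["synth_annotation"]


def synth_annotation(
    L: int = 1_000_000,
    n_intervals: int = 500,
    interval_length: int = 500,
    gap_layout: str = "uniform",
    seed: int = 0,
    chrom: str = "chr1",
) -> Annotation:
    """Place ``n_intervals`` disjoint ``interval_length``-bp intervals on [0, L).

    ``gap_layout="uniform"`` draws uniformly over all valid configurations
    (sorted uniform offsets plus deterministic shifts — a bijection onto start
    tuples with >=1-base separation); ``"fixed"`` spaces intervals evenly.
    Deterministic for a fixed seed.
    """
    if n_intervals < 0 or interval_length < 1:
        raise ValidationError("need n_intervals >= 0 and interval_length >= 1")
    if n_intervals * (interval_length + 1) > L:
        raise ValidationError(
            f"cannot pack {n_intervals} intervals of {interval_length} bp with "
            f">=1-base separation into L = {L}"
        )
    if n_intervals == 0:
        return Annotation(intervals={chrom: np.empty((0, 2), dtype=np.int64)}, lengths={chrom: L})
    if gap_layout == "uniform":
        rng = np.random.default_rng(seed)
        slack = L - n_intervals * (interval_length + 1) + 1
        u = np.sort(rng.integers(0, slack, size=n_intervals))
        starts = u + np.arange(n_intervals, dtype=np.int64) * (interval_length + 1)
    elif gap_layout == "fixed":
        step = L // n_intervals
        starts = np.arange(n_intervals, dtype=np.int64) * step + (step - interval_length) // 2
    else:
        raise ValueError(f"unknown gap_layout {gap_layout!r}")
    intervals = np.column_stack([starts, starts + interval_length])
    return Annotation(intervals={chrom: intervals}, lengths={chrom: L})
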