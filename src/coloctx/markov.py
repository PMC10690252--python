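"""Two-state context-aware Markov chain: training, closed forms, sampling.

The chain generates a binary state sequence S_-1, S_0, ..., S_{L-1}; state 1 at
position i means the induced annotation covers position i. Each context class
label carries its own 2x2 transition matrix; the transition into position i is
governed by the matrix of the class at position i. S_-1 is drawn from the
stationary distribution of the matrix of the class at position 0 and exists
only for notational convenience (it is not part of the annotation and the
transition into position 0 uses it as the previous state).

Training maximizes the likelihood of an observed query annotation by counting,
for each class, the four (previous state, state) transition pair frequencies,
with a pseudocount of 1 per cell to keep all probabilities strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import Annotation, GenomeContext, ValidationError

__all__ = [
    "stationary",
    "nstep",
    "all_zero_prob",
    "ContextAwareMarkovChain",
    "train",
    "sample",
]

_ROW_SUM_TOL = 1e-8


def validate_transition_matrix(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape != (2, 2):
        raise ValidationError(f"transition matrix must be 2x2, got {T.shape}")
    if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
        raise ValidationError("transition probabilities outside [0, 1]")
    if np.any(np.abs(T.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
        raise ValidationError("transition matrix rows must sum to 1")
    return T


def stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution (pi_0, pi_1) of a 2x2 row-stochastic matrix.

    Closed form ``(T10/(1 - T00 + T10), (1 - T00)/(1 - T00 + T10))``. In the
    degenerate absorbing case ``T00 = 1, T10 = 0`` the denominator vanishes and
    the convention (1, 0) is returned.
    """
    denom = 1.0 - T[0, 0] + T[1, 0]
    if denom <= 0.0:
        return np.array([1.0, 0.0])
    return np.array([T[1, 0] / denom, (1.0 - T[0, 0]) / denom])


def nstep(T: np.ndarray, n: int) -> np.ndarray:
    """n-step transition matrix T^n in O(1) via the 2-state eigendecomposition.

    ``T^n = Pi + (1 - a - b)^n (I - Pi)`` where a = T01, b = T10 and Pi has the
    stationary vector in both rows.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.eye(2)
    a, b = T[0, 1], T[1, 0]
    s = a + b
    if s <= 0.0:
        return np.eye(2)
    pi = np.array([b / s, a / s])
    r = 1.0 - s
    r = min(1.0, max(-1.0, r))
    Pi = np.tile(pi, (2, 1))
    out = Pi + (r**n) * (np.eye(2) - Pi)
    return np.clip(out, 0.0, 1.0)


def all_zero_prob(T: np.ndarray, x: int, n: int) -> float:
    """Probability that the next n states are all 0 given the current state x."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(T[x, 0] * T[0, 0] ** (n - 1))


@dataclass
class ContextAwareMarkovChain:
    """Per-class transition matrices plus, when trained, the raw counts."""

    matrices: dict[str, np.ndarray]
    counts: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.matrices = {
            lab: validate_transition_matrix(T) for lab, T in self.matrices.items()
        }

    @property
    def labels(self) -> set[str]:
        return set(self.matrices)

    def matrix(self, label: str) -> np.ndarray:
        try:
            return self.matrices[label]
        except KeyError:
            raise ValidationError(
                f"chain has no transition matrix for context class {label!r}"
            ) from None

    def to_table(self, path: str | Path) -> None:
        """Serialize to a plain-text TSV (label, 4 matrix entries, 4 counts)."""
        with open(path, "w") as fh:
            fh.write("label\tt00\tt01\tt10\tt11\tc00\tc01\tc10\tc11\n")
            for lab in sorted(self.matrices):
                T = self.matrices[lab]
                c = (
                    self.counts[lab]
                    if self.counts is not None and lab in self.counts
                    else np.zeros((2, 2), dtype=np.int64)
                )
                fh.write(
                    f"{lab}\t{float(T[0, 0])!r}\t{float(T[0, 1])!r}"
                    f"\t{float(T[1, 0])!r}\t{float(T[1, 1])!r}"
                    f"\t{c[0, 0]}\t{c[0, 1]}\t{c[1, 0]}\t{c[1, 1]}\n"
                )

    @classmethod
    def from_table(cls, path: str | Path) -> "ContextAwareMarkovChain":
        matrices: dict[str, np.ndarray] = {}
        counts: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("label\t"):
                raise ValidationError(f"{path}: not a chain table")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValidationError(f"{path}: malformed chain table row")
                lab = parts[0]
                vals = [float(x) for x in parts[1:5]]
                matrices[lab] = np.array(vals).reshape(2, 2)
                counts[lab] = np.array([int(x) for x in parts[5:9]]).reshape(2, 2)
        return cls(matrices=matrices, counts=counts)


def _coverage_below(
    begins: np.ndarray, ends: np.ndarray, cum: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Total size of union([b+1, e)) intersected with [0, x), vectorized in x.

    ``begins``/``ends`` are sorted disjoint query intervals; ``cum`` is the
    cumulative sum of (e - b - 1). Used to count within-interval (1,1)
    transition pairs falling in a context segment.
    """
    j = np.searchsorted(ends, x, side="right")
    full = cum[j]
    partial = np.zeros_like(full)
    has_part = j < len(begins)
    jj = np.clip(j, 0, max(len(begins) - 1, 0))
    if len(begins):
        partial = np.where(has_part, np.clip(x - (begins[jj] + 1), 0, None), 0)
    return full + partial


def train(
    Q: Annotation,
    ctx: GenomeContext,
    pseudocount: int = 1,
) -> ContextAwareMarkovChain:
    """Fit per-class transition matrices from a query annotation.

    The transition pair at position i (states at i-1 and i, for i from 1 to
    L-1 on each chromosome) is attributed to the class of the *destination*
    position i. Counts are pooled across chromosomes, a pseudocount is added
    to every (class, s, s') cell, and rows are normalized. Runs in time
    proportional to the number of query intervals plus class boundaries, via
    run-length arithmetic.
    """
    for chrom in ctx.chroms:
        if chrom in Q.lengths and Q.lengths[chrom] != ctx.lengths[chrom]:
            raise ValidationError(
                f"{chrom}: annotation length {Q.lengths[chrom]} != context "
                f"length {ctx.lengths[chrom]}"
            )
    label_list = sorted(ctx.label_set())
    label_idx = {lab: i for i, lab in enumerate(label_list)}
    counts = np.zeros((len(label_list), 2, 2), dtype=np.int64)
    for chrom in ctx.chroms:
        L = ctx.lengths[chrom]
        if L < 2:
            continue
        arr = Q.get(chrom)
        begins = arr[:, 0]
        ends = arr[:, 1]
        cum = np.concatenate([[0], np.cumsum(np.maximum(ends - begins - 1, 0))])
        seg_starts = ctx.starts[chrom]
        seg_ends = np.append(seg_starts[1:], L)
        lo = np.maximum(seg_starts, 1)
        hi = seg_ends
        total = np.maximum(hi - lo, 0)
        n01 = np.searchsorted(begins, hi, "left") - np.searchsorted(begins, lo, "left")
        n10 = np.searchsorted(ends, hi, "left") - np.searchsorted(ends, lo, "left")
        n11 = _coverage_below(begins, ends, cum, hi) - _coverage_below(
            begins, ends, cum, lo
        )
        n00 = total - n01 - n10 - n11
        idx = np.array([label_idx[l] for l in ctx.labels[chrom]])
        np.add.at(counts, (idx, 0, 0), n00)
        np.add.at(counts, (idx, 0, 1), n01)
        np.add.at(counts, (idx, 1, 0), n10)
        np.add.at(counts, (idx, 1, 1), n11)
    counts += pseudocount
    matrices = {}
    count_map = {}
    for lab, i in label_idx.items():
        c = counts[i].astype(float)
        matrices[lab] = c / c.sum(axis=1, keepdims=True)
        count_map[lab] = counts[i].copy()
    return ContextAwareMarkovChain(matrices=matrices, counts=count_map)


def sample(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    rng: int | np.random.Generator,
) -> Annotation:
    """Draw one annotation from the chain under the given context.

    Per chromosome: S_-1 is drawn from the stationary distribution of the
    matrix of the first segment's class, then states advance position by
    position under the class at each position. Implemented by sampling
    geometric sojourn lengths within each same-class run (memorylessness makes
    truncation at run ends exact; a fresh sojourn is drawn after each class
    boundary, where the transition matrix changes anyway). Deterministic for a
    fixed seed; chromosomes are processed in sorted name order.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    missing = ctx.label_set() - chain.labels
    if missing:
        raise ValidationError(f"chain lacks matrices for context classes {sorted(missing)}")
    intervals: dict[str, np.ndarray] = {}
    for chrom in ctx.chroms:
        L = ctx.lengths[chrom]
        pi = stationary(chain.matrix(ctx.first_label(chrom)))
        state = 1 if rng.random() < pi[1] else 0
        frag_b: list[int] = []
        frag_e: list[int] = []
        pos = 0
        for rs, re, lab in ctx.runs(chrom):
            T = chain.matrix(lab)
            while pos < re:
                stay = T[state, state]
                if stay >= 1.0:
                    g = re - pos
                else:
                    g = int(rng.geometric(1.0 - stay)) - 1
                take = min(g, re - pos)
                if state == 1 and take > 0:
                    if frag_e and frag_e[-1] == pos:
                        frag_e[-1] = pos + take
                    else:
                        frag_b.append(pos)
                        frag_e.append(pos + take)
                pos += take
                if g == take and pos < re:
                    state = 1 - state
                    if state == 1:
                        if frag_e and frag_e[-1] == pos:
                            frag_e[-1] = pos + 1
                        else:
                            frag_b.append(pos)
                            frag_e.append(pos + 1)
                    pos += 1
        intervals[chrom] = np.column_stack([frag_b, frag_e]).astype(np.int64) if frag_b else np.empty((0, 2), dtype=np.int64)
    return Annotation(intervals=intervals, lengths=dict(ctx.lengths))
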