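"""Exact mean and variance of separable colocalization statistics.

A statistic is *separable* when it is a sum over reference intervals of
contributions that depend only on the query states inside each interval; the
number of reference intervals overlapping the query (``overlaps``, K) and the
number of jointly covered bases (``bases``, B) are the two shipped instances.

The engine summarizes each reference interval and each gap between intervals
by a *two-sided plumbus*: the contribution's conditional mean and variance
plus the boundary-to-boundary transition probabilities, all conditioned on the
chain state just before the piece starts (x) and at its last position (y).
Plumbuses of adjacent pieces combine associatively using the conditional
independence of Markov states across a shared boundary and the law of total
variance; folding across a chromosome and removing the boundary conditioning
with the stationary initial distribution yields the exact mean and variance of
the total statistic. Work is O(|R| + c) plumbus combinations for K and
O((|R| + c) log t) for B, where c is the number of context class boundaries
and t the longest same-class stretch inside a reference interval (handled by a
doubling ladder of power-of-two plumbuses per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import Annotation, GenomeContext, ValidationError
from .markov import ContextAwareMarkovChain, all_zero_prob, nstep, stationary

__all__ = [
    "TwoSidedPlumbus",
    "MomentResult",
    "identity_plumbus",
    "gap_plumbus",
    "overlap_interval_plumbus",
    "bases_interval_plumbus",
    "combine",
    "finalize",
    "moments",
]

_PSI_ROW_TOL = 1e-8


@dataclass(slots=True)
class TwoSidedPlumbus:
    """Conditional moments and boundary transitions for one genome piece.

    ``mu[x, y]``, ``var[x, y]``: mean and variance of the piece's contribution
    given state x just before the piece and state y at its last position.
    ``psi[x, y]``: probability of reaching y from x across the piece. ``span``
    is the piece length in bp; ``start``/``end`` are genome coordinates when
    the piece is anchored (ladder building blocks are unanchored).
    Cells with ``psi[x, y] == 0`` are unreachable; their mu/var are sentinel
    zeros and they receive zero weight downstream.
    """

    mu: np.ndarray
    var: np.ndarray
    psi: np.ndarray
    span: int
    start: int | None = None
    end: int | None = None

    def check_health(self) -> None:
        rows = self.psi.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _PSI_ROW_TOL):
            raise FloatingPointError(
                f"plumbus boundary transitions lost stochasticity: row sums {rows}"
            )


class CombineCounter:
    """Counts plumbus combinations; exposed for complexity tests."""

    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0


def identity_plumbus(start: int | None = None) -> TwoSidedPlumbus:
    """Length-0 piece: the neutral element of :func:`combine`."""
    return TwoSidedPlumbus(
        mu=np.zeros((2, 2)),
        var=np.zeros((2, 2)),
        psi=np.eye(2),
        span=0,
        start=start,
        end=start,
    )


def _span_psi(chain: ContextAwareMarkovChain, runs: Sequence[tuple[int, str]]) -> np.ndarray:
    psi = np.eye(2)
    for n, lab in runs:
        psi = psi @ nstep(chain.matrix(lab), n)
    return psi


def gap_plumbus(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    start: int,
    end: int,
) -> TwoSidedPlumbus:
    """Plumbus of a gap between reference intervals: zero contribution.

    Only the boundary transition matrix is non-trivial; it is the product of
    n-step matrices over the gap's maximal same-class runs.
    """
    runs = ctx.runs_between(chrom, start, end)
    return TwoSidedPlumbus(
        mu=np.zeros((2, 2)),
        var=np.zeros((2, 2)),
        psi=_span_psi(chain, runs),
        span=end - start,
        start=start,
        end=end,
    )


def overlap_interval_plumbus(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    start: int,
    end: int,
) -> TwoSidedPlumbus:
    """Plumbus of a reference interval for the overlap-count statistic K.

    The contribution is the indicator that any state inside [start, end) is 1.
    With z(x) = Pr[all states 0 | previous state x] the conditional mean given
    final state y = 0 is 1 - z(x)/psi(x->0) and the contribution is Bernoulli,
    so the conditional variance is mu(1 - mu); y = 1 forces an overlap.
    """
    if end <= start:
        raise ValidationError("reference interval must be non-empty")
    runs = ctx.runs_between(chrom, start, end)
    psi = _span_psi(chain, runs)
    z = np.empty(2)
    for x in (0, 1):
        (n0, lab0) = runs[0]
        p = all_zero_prob(chain.matrix(lab0), x, n0)
        for n, lab in runs[1:]:
            p *= chain.matrix(lab)[0, 0] ** n
        z[x] = p
    mu = np.ones((2, 2))
    var = np.zeros((2, 2))
    for x in (0, 1):
        if psi[x, 0] > 0.0:
            m = 1.0 - z[x] / psi[x, 0]
            mu[x, 0] = min(max(m, 0.0), 1.0)
        else:
            mu[x, 0] = 1.0  # unreachable cell; zero weight downstream
        var[x, 0] = mu[x, 0] * (1.0 - mu[x, 0])
    return TwoSidedPlumbus(mu=mu, var=var, psi=psi, span=end - start, start=start, end=end)


def _single_position_plumbus(T: np.ndarray) -> TwoSidedPlumbus:
    # contribution for B at one position is the state itself
    mu = np.array([[0.0, 1.0], [0.0, 1.0]])
    return TwoSidedPlumbus(mu=mu, var=np.zeros((2, 2)), psi=T.copy(), span=1)


def combine(
    left: TwoSidedPlumbus,
    right: TwoSidedPlumbus,
    counter: CombineCounter | None = None,
) -> TwoSidedPlumbus:
    """Merge two adjacent plumbuses across their shared boundary state.

    The shared boundary state m (the last state of the left piece, equally the
    conditioning state of the right piece) is summed out: boundary transitions
    multiply as matrices, conditional means add under the posterior weight of
    m, and conditional variances follow the law of total variance over m.
    """
    if (
        left.end is not None
        and right.start is not None
        and left.end != right.start
    ):
        raise ValidationError(
            f"cannot combine plumbuses spanning [{left.start}, {left.end}) and "
            f"[{right.start}, {right.end}): not adjacent"
        )
    if counter is not None:
        counter.n += 1
    psi = left.psi @ right.psi
    num = left.psi[:, :, None] * right.psi[None, :, :]  # (x, m, y)
    denom = psi[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0.0, num / np.where(denom > 0.0, denom, 1.0), 0.0)
    msum = left.mu[:, :, None] + right.mu[None, :, :]
    mu = np.einsum("xmy,xmy->xy", w, msum)
    var = (
        np.einsum("xmy,xmy->xy", w, left.var[:, :, None] + right.var[None, :, :])
        + np.einsum("xmy,xmy->xy", w, msum * msum)
        - mu * mu
    )
    np.maximum(var, 0.0, out=var)
    reachable = psi > 0.0
    mu = np.where(reachable, mu, 0.0)
    var = np.where(reachable, var, 0.0)
    start = left.start
    end = right.end
    if left.start is None or right.end is None:
        start = end = None
    return TwoSidedPlumbus(
        mu=mu, var=var, psi=psi, span=left.span + right.span, start=start, end=end
    )


class _BasesLadder:
    """Per-class cache of power-of-two plumbuses for the shared-bases statistic."""

    def __init__(self, chain: ContextAwareMarkovChain, counter: CombineCounter | None):
        self.chain = chain
        self.counter = counter
        self._cache: dict[tuple[str, int], TwoSidedPlumbus] = {}

    def power(self, label: str, k: int) -> TwoSidedPlumbus:
        key = (label, k)
        if key not in self._cache:
            if k == 0:
                self._cache[key] = _single_position_plumbus(self.chain.matrix(label))
            else:
                half = self.power(label, k - 1)
                self._cache[key] = combine(half, half, self.counter)
        return self._cache[key]

    def run(self, label: str, n: int) -> TwoSidedPlumbus:
        """Plumbus for n consecutive positions of one class, O(log n) combines."""
        acc: TwoSidedPlumbus | None = None
        k = 0
        while n:
            if n & 1:
                p = self.power(label, k)
                acc = p if acc is None else combine(acc, p, self.counter)
            n >>= 1
            k += 1
        assert acc is not None
        return acc


def bases_interval_plumbus(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    start: int,
    end: int,
    ladder: _BasesLadder | None = None,
    counter: CombineCounter | None = None,
) -> TwoSidedPlumbus:
    """Plumbus of a reference interval for the shared-bases statistic B.

    Equivalent to folding end-start single-position plumbuses; computed per
    maximal same-class run via the doubling ladder (combine along the binary
    representation of the run length), then across runs.
    """
    if end <= start:
        raise ValidationError("reference interval must be non-empty")
    if ladder is None:
        ladder = _BasesLadder(chain, counter)
    acc: TwoSidedPlumbus | None = None
    for n, lab in ctx.runs_between(chrom, start, end):
        p = ladder.run(lab, n)
        acc = p if acc is None else combine(acc, p, ladder.counter)
    assert acc is not None
    # re-anchor without mutating cached ladder entries
    return TwoSidedPlumbus(
        mu=acc.mu, var=acc.var, psi=acc.psi, span=acc.span, start=start, end=end
    )


def finalize(full: TwoSidedPlumbus, init: np.ndarray) -> tuple[float, float]:
    """Remove the boundary conditioning of a whole-chromosome plumbus.

    ``init`` is the state distribution at position -1 (the stationary vector
    of the first segment's class). The joint weight of boundary pair (x, y) is
    init[x] * psi[x -> y]; the law of total variance over (x, y) then gives
    the unconditional mean and variance.
    """
    init = np.asarray(init, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValidationError("initial distribution does not sum to 1")
    full.check_health()
    p = init[:, None] * full.psi
    mean = float((p * full.mu).sum())
    var = float((p * full.var).sum() + (p * full.mu**2).sum() - mean**2)
    return mean, max(var, 0.0)


@dataclass
class MomentResult:
    """Exact null mean/variance of a separable statistic, per chromosome and total."""

    statistic: str
    mean: float
    variance: float
    per_chrom: dict[str, tuple[float, float]]
    combine_calls: int


def _chrom_moments(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    intervals: np.ndarray,
    statistic: str,
) -> tuple[float, float, int]:
    counter = CombineCounter()
    ladder = _BasesLadder(chain, counter) if statistic == "bases" else None
    acc = identity_plumbus(start=0)
    pos = 0
    for b, e in intervals:
        b, e = int(b), int(e)
        if b > pos:
            acc = combine(acc, gap_plumbus(chain, ctx, chrom, pos, b), counter)
        if statistic == "overlaps":
            p = overlap_interval_plumbus(chain, ctx, chrom, b, e)
        else:
            p = bases_interval_plumbus(chain, ctx, chrom, b, e, ladder=ladder)
        acc = combine(acc, p, counter)
        pos = e
    L = ctx.lengths[chrom]
    if pos < L:
        acc = combine(acc, gap_plumbus(chain, ctx, chrom, pos, L), counter)
    init = stationary(chain.matrix(ctx.first_label(chrom)))
    mean, var = finalize(acc, init)
    return mean, var, counter.n


def moments(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    R: Annotation,
    statistic: str = "overlaps",
    threads: int = 1,
) -> MomentResult:
    """Exact null mean and variance of K or B over all chromosomes.

    Chromosomes are independent under the model, so genome totals are sums of
    per-chromosome means and variances. Chromosomes without reference
    intervals contribute identically zero and are skipped.
    """
    if statistic not in ("overlaps", "bases"):
        raise ValueError(f"unknown statistic {statistic!r}")
    missing = ctx.label_set() - chain.labels
    if missing:
        raise ValidationError(f"chain lacks matrices for context classes {sorted(missing)}")
    jobs = [
        (chrom, R.get(chrom))
        for chrom in ctx.chroms
        if len(R.get(chrom))
    ]
    if threads > 1 and len(jobs) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(
                pool.map(
                    lambda job: _chrom_moments(chain, ctx, job[0], job[1], statistic),
                    jobs,
                )
            )
    else:
        results = [_chrom_moments(chain, ctx, c, arr, statistic) for c, arr in jobs]
    per_chrom = {
        chrom: (m, v) for (chrom, _), (m, v, _) in zip(jobs, results)
    }
    total_mean = float(sum(m for m, _, _ in results))
    total_var = float(sum(v for _, v, _ in results))
    calls = int(sum(n for _, _, n in results))
    return MomentResult(
        statistic=statistic,
        mean=total_mean,
        variance=total_var,
        per_chrom=per_chrom,
        combine_calls=calls,
    )
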