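"""Exact null probability mass functions of the colocalization statistics.

A quadratic-time dynamic program sweeps each chromosome left to right,
carrying the joint distribution of (state at the current boundary position,
statistic value so far). Gaps between reference intervals only update the
state marginal; reference intervals branch on their contribution. This is
both a user-facing exact mode, recommended for small reference annotations
where the normal approximation's extreme tail is unreliable, and the
verification oracle for the moment engine. A full enumeration over all state
sequences for tiny chromosomes serves as the independent ground truth for
both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import Annotation, GenomeContext, ValidationError
from .markov import ContextAwareMarkovChain, all_zero_prob, nstep, stationary

__all__ = ["PMF", "exact_pmf_overlaps", "exact_pmf_bases", "brute_force"]

OVERLAPS_SUPPORT_WARN = 50_000
BASES_LENGTH_GUARD = 10_000


@dataclass
class PMF:
    """Distribution of a nonnegative integer statistic: probs[k] = Pr[A = k]."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-12):
            raise ValidationError("PMF has negative probabilities")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"PMF sums to {total}, not 1")

    @property
    def support_max(self) -> int:
        return len(self.probs) - 1

    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)

    def variance(self) -> float:
        k = np.arange(len(self.probs))
        m = self.mean()
        return float((k - m) ** 2 @ self.probs)

    def p_enrichment(self, observed: int) -> float:
        """Right tail Pr[A >= observed], including the observed value."""
        if observed <= 0:
            return 1.0
        if observed > self.support_max:
            return 0.0
        return float(self.probs[observed:].sum())

    def p_depletion(self, observed: int) -> float:
        """Left tail Pr[A <= observed]."""
        if observed < 0:
            return 0.0
        return float(self.probs[: min(observed, self.support_max) + 1].sum())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("value\tprobability\n")
            for k, p in enumerate(self.probs):
                fh.write(f"{k}\t{float(p)!r}\n")


def _gap_update(
    d: np.ndarray,
    chain: ContextAwareMarkovChain,
    runs: list[tuple[int, str]],
) -> np.ndarray:
    G = np.eye(2)
    for n, lab in runs:
        G = G @ nstep(chain.matrix(lab), n)
    return G.T @ d


def _interval_psi_z(
    chain: ContextAwareMarkovChain, runs: list[tuple[int, str]]
) -> tuple[np.ndarray, np.ndarray]:
    psi = np.eye(2)
    for n, lab in runs:
        psi = psi @ nstep(chain.matrix(lab), n)
    z = np.empty(2)
    for x in (0, 1):
        n0, lab0 = runs[0]
        p = all_zero_prob(chain.matrix(lab0), x, n0)
        for n, lab in runs[1:]:
            p *= chain.matrix(lab)[0, 0] ** n
        z[x] = p
    return psi, z


def _chrom_pmf_overlaps(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    intervals: np.ndarray,
) -> np.ndarray:
    nR = len(intervals)
    pi = stationary(chain.matrix(ctx.first_label(chrom)))
    d = np.zeros((2, nR + 1))
    d[:, 0] = pi
    pos = 0
    for b, e in intervals:
        b, e = int(b), int(e)
        if b > pos:
            d = _gap_update(d, chain, ctx.runs_between(chrom, pos, b))
        psi, z = _interval_psi_z(chain, ctx.runs_between(chrom, b, e))
        to1 = psi[0, 1] * d[0] + psi[1, 1] * d[1]
        to0_hit = np.clip(psi[0, 0] - z[0], 0.0, None) * d[0] + np.clip(
            psi[1, 0] - z[1], 0.0, None
        ) * d[1]
        to0_miss = z[0] * d[0] + z[1] * d[1]
        new = np.zeros_like(d)
        new[1, 1:] = to1[:-1]
        new[0, 1:] = to0_hit[:-1]
        new[0, :] += to0_miss
        d = new
        pos = e
    # trailing gap does not change the statistic marginal
    return d.sum(axis=0)


def exact_pmf_overlaps(
    chain: ContextAwareMarkovChain, ctx: GenomeContext, R: Annotation
) -> PMF:
    """Exact PMF of the overlap count K under the trained null.

    Quadratic in the per-chromosome reference interval count; per-chromosome
    PMFs are convolved into the genome total (chromosome independence).
    """
    pmf = np.array([1.0])
    for chrom in ctx.chroms:
        intervals = R.get(chrom)
        if not len(intervals):
            continue
        if len(intervals) > OVERLAPS_SUPPORT_WARN:
            warnings.warn(
                f"{chrom}: exact PMF over {len(intervals)} reference intervals is "
                "quadratic-time; consider the moments mode",
                stacklevel=2,
            )
        pmf = np.convolve(pmf, _chrom_pmf_overlaps(chain, ctx, chrom, intervals))
    return PMF(pmf)


def _chrom_pmf_bases(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    chrom: str,
    intervals: np.ndarray,
) -> np.ndarray:
    tot = int((intervals[:, 1] - intervals[:, 0]).sum())
    pi = stationary(chain.matrix(ctx.first_label(chrom)))
    d = np.zeros((2, tot + 1))
    d[:, 0] = pi
    pos = 0
    for b, e in intervals:
        b, e = int(b), int(e)
        if b > pos:
            d = _gap_update(d, chain, ctx.runs_between(chrom, pos, b))
        for n, lab in ctx.runs_between(chrom, b, e):
            T = chain.matrix(lab)
            for _ in range(n):
                to0 = T[0, 0] * d[0] + T[1, 0] * d[1]
                to1 = T[0, 1] * d[0] + T[1, 1] * d[1]
                d[0] = to0
                d[1, 1:] = to1[:-1]
                d[1, 0] = 0.0
        pos = e
    return d.sum(axis=0)


def exact_pmf_bases(
    chain: ContextAwareMarkovChain, ctx: GenomeContext, R: Annotation
) -> PMF:
    """Exact PMF of the shared-bases count B, quadratic in total reference length."""
    total_len = R.covered_bases()
    if total_len > BASES_LENGTH_GUARD:
        raise ValidationError(
            f"total reference length {total_len} exceeds the exact-mode guard "
            f"({BASES_LENGTH_GUARD}); use the moments mode instead"
        )
    pmf = np.array([1.0])
    for chrom in ctx.chroms:
        intervals = R.get(chrom)
        if not len(intervals):
            continue
        pmf = np.convolve(pmf, _chrom_pmf_bases(chain, ctx, chrom, intervals))
    return PMF(pmf)


def brute_force(
    chain: ContextAwareMarkovChain,
    ctx: GenomeContext,
    R: Annotation,
    statistic: str = "overlaps",
    L_max: int = 16,
) -> PMF:
    """Ground-truth PMF by enumerating all 2^(L+1) state sequences.

    Single chromosome only. Each sequence (including the notational state at
    position -1) is weighted by the generative product probability and the
    statistic evaluated on the induced annotation; exact by construction.
    """
    if len(ctx.lengths) != 1:
        raise ValidationError("brute force enumeration handles a single chromosome")
    chrom = next(iter(ctx.lengths))
    L = ctx.lengths[chrom]
    if L > L_max:
        raise ValidationError(f"L = {L} exceeds brute-force cap {L_max}")
    labels: list[str] = []
    for s, e, lab in ctx.runs(chrom):
        labels.extend([lab] * (e - s))
    Tarr = np.stack([chain.matrix(l) for l in labels])  # (L, 2, 2)
    pi = stationary(chain.matrix(labels[0]))
    n = 1 << (L + 1)
    seq = (np.arange(n)[:, None] >> np.arange(L + 1)[None, :]) & 1  # col 0 = S_-1
    prob = pi[seq[:, 0]] * np.prod(
        Tarr[np.arange(L)[None, :], seq[:, :-1], seq[:, 1:]], axis=1
    )
    states = seq[:, 1:]
    intervals = R.get(chrom)
    if statistic == "overlaps":
        value = np.zeros(n, dtype=np.int64)
        for b, e in intervals:
            value += states[:, b:e].any(axis=1)
    elif statistic == "bases":
        value = np.zeros(n, dtype=np.int64)
        for b, e in intervals:
            value += states[:, b:e].sum(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    pmf = np.bincount(value, weights=prob)
    return PMF(pmf)
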