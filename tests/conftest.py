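"""Shared helpers: random tiny instances checkable by full enumeration."""

from __future__ import annotations

import numpy as np
import pytest

from coloctx import Annotation, ContextAwareMarkovChain, GenomeContext


def random_chain(rng: np.random.Generator, labels) -> ContextAwareMarkovChain:
    """Chain with strictly positive random transition probabilities."""
    mats = {}
    for lab in labels:
        T = rng.uniform(0.05, 0.95, size=(2, 2))
        T /= T.sum(axis=1, keepdims=True)
        mats[lab] = T
    return ContextAwareMarkovChain(mats)


def random_context(
    rng: np.random.Generator, L: int, max_classes: int = 3, chrom: str = "chr1"
) -> GenomeContext:
    n_class = int(rng.integers(1, max_classes + 1))
    n_seg = int(rng.integers(1, min(4, L) + 1))
    cuts = (
        np.sort(rng.choice(np.arange(1, L), size=min(n_seg - 1, L - 1), replace=False))
        if n_seg > 1
        else np.array([], dtype=np.int64)
    )
    starts = np.concatenate([[0], cuts]).astype(np.int64)
    labels = [f"c{int(rng.integers(n_class))}" for _ in starts]
    return GenomeContext(starts={chrom: starts}, labels={chrom: labels}, lengths={chrom: L})


def random_reference(
    rng: np.random.Generator, L: int, max_intervals: int = 3, chrom: str = "chr1"
) -> Annotation:
    nR = int(rng.integers(0, max_intervals + 1))
    pts = np.sort(rng.choice(np.arange(L + 1), size=min(2 * nR, L + 1), replace=False))
    iv = pts[: 2 * (len(pts) // 2)].reshape(-1, 2)
    iv = iv[iv[:, 0] < iv[:, 1]]
    return Annotation(intervals={chrom: iv}, lengths={chrom: L})


def random_tiny_instance(rng: np.random.Generator, L_max: int = 14):
    """(chain, ctx, R) on a single chromosome short enough for enumeration."""
    L = int(rng.integers(4, L_max + 1))
    ctx = random_context(rng, L)
    chain = random_chain(rng, ctx.label_set())
    R = random_reference(rng, L)
    return chain, ctx, R


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
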