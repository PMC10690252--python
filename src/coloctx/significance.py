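"""Z-scores, enrichment/depletion p-values, and end-to-end evaluation.

The null hypothesis is that the query annotation was generated by the
context-aware Markov chain whose per-class transition matrices are trained
from the query itself; the reference annotation is fixed and never enters
training. The observed statistic is converted to a Z-score using the exact
null mean and variance and to p-values through the standard normal CDF
(normal mode), or compared against the full exact PMF (exact mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import engine, exact
from .intervals import Annotation, GenomeContext, ValidationError
from .markov import ContextAwareMarkovChain, train

__all__ = [
    "observed_statistic",
    "z_score",
    "normal_pvalues",
    "TailPValues",
    "ColocalizationResult",
    "evaluate",
    "results_table",
    "SMALL_REFERENCE_THRESHOLD",
]

_LN10 = math.log(10.0)

#: below this reference interval count the normal tail may be conservative;
#: the exact mode is recommended instead
SMALL_REFERENCE_THRESHOLD = 500


def observed_statistic(
    R: Annotation, Q: Annotation, statistic: str = "overlaps", chrom: str | None = None
) -> int:
    """Observed K (reference intervals overlapping Q) or B (jointly covered bases)."""
    if statistic not in ("overlaps", "bases"):
        raise ValueError(f"unknown statistic {statistic!r}")
    chroms = [chrom] if chrom is not None else sorted(set(R.intervals) & set(Q.intervals))
    total = 0
    for c in chroms:
        r = R.get(c)
        q = Q.get(c)
        if not len(r) or not len(q):
            continue
        qb, qe = q[:, 0], q[:, 1]
        if statistic == "overlaps":
            # the first query interval ending after r_begin must start before r_end
            idx = np.searchsorted(qe, r[:, 0], side="right")
            hit = (idx < len(qb)) & (qb[np.minimum(idx, len(qb) - 1)] < r[:, 1])
            total += int(hit.sum())
        else:
            cum = np.concatenate([[0], np.cumsum(qe - qb)])

            def cov(x: np.ndarray) -> np.ndarray:
                j = np.searchsorted(qe, x, side="right")
                part = np.where(
                    j < len(qb),
                    np.clip(x - qb[np.minimum(j, len(qb) - 1)], 0, None),
                    0,
                )
                return cum[j] + part

            total += int((cov(r[:, 1]) - cov(r[:, 0])).sum())
    return total


def z_score(observed: float, mean: float, variance: float) -> float:
    """Standard score (observed - mean) / sqrt(variance); NaN when variance is 0."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return math.nan
    return (observed - mean) / math.sqrt(variance)


class TailPValues(NamedTuple):
    enrichment: float
    depletion: float
    log10_enrichment: float
    log10_depletion: float


def normal_pvalues(z: float) -> TailPValues:
    """Upper/lower standard-normal tail p-values with stable log10 values.

    The log10 values come from the normal log-tail directly, so extreme
    Z-scores report a meaningful magnitude even where the linear-scale value
    underflows to 0.
    """
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return TailPValues(
        enrichment=float(stats.norm.sf(z)),
        depletion=float(stats.norm.cdf(z)),
        log10_enrichment=float(stats.norm.logsf(z) / _LN10),
        log10_depletion=float(stats.norm.logcdf(z) / _LN10),
    )


@dataclass
class ColocalizationResult:
    """Everything needed to report and reproduce one colocalization test."""

    statistic: str
    observed: int
    null_mean: float
    null_variance: float
    z: float
    p_enrichment: float
    p_depletion: float
    log10_p_enrichment: float
    log10_p_depletion: float
    mode: str
    status: str
    per_chrom: pd.DataFrame
    chain: ContextAwareMarkovChain | None = None
    pmf: exact.PMF | None = None
    combine_calls: int = 0

    def to_frame(self) -> pd.DataFrame:
        genome = pd.DataFrame(
            [
                {
                    "chrom": "genome",
                    "statistic": self.statistic,
                    "observed": self.observed,
                    "null_mean": self.null_mean,
                    "null_var": self.null_variance,
                    "z": self.z,
                    "p_enrich": self.p_enrichment,
                    "p_deplete": self.p_depletion,
                    "log10_p_enrich": self.log10_p_enrichment,
                    "log10_p_deplete": self.log10_p_depletion,
                    "mode": self.mode,
                    "status": self.status,
                }
            ]
        )
        if self.per_chrom.empty:
            return genome
        return pd.concat([genome, self.per_chrom], ignore_index=True)


def _tails_normal(observed: float, mean: float, variance: float) -> tuple[float, TailPValues | None, str]:
    z = z_score(observed, mean, variance)
    if math.isnan(z):
        return z, None, "degenerate"
    return z, normal_pvalues(z), "ok"


def evaluate(
    Q: Annotation,
    R: Annotation,
    ctx: GenomeContext | None = None,
    statistic: str = "overlaps",
    mode: str = "normal",
    pseudocount: int = 1,
    small_r_threshold: int = SMALL_REFERENCE_THRESHOLD,
    threads: int = 1,
) -> ColocalizationResult:
    """Train the null on (Q, ctx), then test colocalization of Q with R.

    With ``ctx=None`` a single-class context covering the whole genome is
    used, which reduces the model to a plain two-state Markov chain null.
    ``mode="normal"`` uses the exact moments with a normal tail;
    ``mode="exact"`` computes the full PMF (quadratic time, guarded).
    """
    if mode not in ("normal", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if ctx is None:
        ctx = GenomeContext.single_class(Q.lengths)
    for c, L in R.lengths.items():
        if c in ctx.lengths and ctx.lengths[c] != L:
            raise ValidationError(f"{c}: reference length {L} != context length {ctx.lengths[c]}")
    chain = train(Q, ctx, pseudocount=pseudocount)
    observed = observed_statistic(R, Q, statistic)
    if mode == "normal" and R.n_intervals() < small_r_threshold:
        warnings.warn(
            f"reference has only {R.n_intervals()} intervals; the normal "
            "approximation can be conservative in the extreme tail — the exact "
            "mode is recommended for small references",
            stacklevel=2,
        )
    rows = []
    pmf = None
    combine_calls = 0
    if mode == "normal":
        mom = engine.moments(chain, ctx, R, statistic=statistic, threads=threads)
        mean, var = mom.mean, mom.variance
        combine_calls = mom.combine_calls
        z, tails, status = _tails_normal(observed, mean, var)
        for chrom_name, (m, v) in sorted(mom.per_chrom.items()):
            obs_c = observed_statistic(R, Q, statistic, chrom=chrom_name)
            zc, tc, sc = _tails_normal(obs_c, m, v)
            rows.append(
                {
                    "chrom": chrom_name,
                    "statistic": statistic,
                    "observed": obs_c,
                    "null_mean": m,
                    "null_var": v,
                    "z": zc,
                    "p_enrich": tc.enrichment if tc else math.nan,
                    "p_deplete": tc.depletion if tc else math.nan,
                    "log10_p_enrich": tc.log10_enrichment if tc else math.nan,
                    "log10_p_deplete": tc.log10_depletion if tc else math.nan,
                    "mode": mode,
                    "status": sc,
                }
            )
    else:
        if statistic == "overlaps":
            pmf = exact.exact_pmf_overlaps(chain, ctx, R)
        else:
            pmf = exact.exact_pmf_bases(chain, ctx, R)
        mean, var = pmf.mean(), pmf.variance()
        z = z_score(observed, mean, var)
        status = "ok" if var > 0 else "degenerate"
        tails = None
        if status == "ok":
            pe = pmf.p_enrichment(observed)
            pd_ = pmf.p_depletion(observed)
            tails = TailPValues(
                enrichment=pe,
                depletion=pd_,
                log10_enrichment=math.log10(pe) if pe > 0 else -math.inf,
                log10_depletion=math.log10(pd_) if pd_ > 0 else -math.inf,
            )
    if tails is None:
        tails = TailPValues(math.nan, math.nan, math.nan, math.nan)
    per_chrom = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "statistic",
            "observed",
            "null_mean",
            "null_var",
            "z",
            "p_enrich",
            "p_deplete",
            "log10_p_enrich",
            "log10_p_deplete",
            "mode",
            "status",
        ],
    )
    return ColocalizationResult(
        statistic=statistic,
        observed=observed,
        null_mean=mean,
        null_variance=var,
        z=z,
        p_enrichment=tails.enrichment,
        p_depletion=tails.depletion,
        log10_p_enrichment=tails.log10_enrichment,
        log10_p_depletion=tails.log10_depletion,
        mode=mode,
        status=status,
        per_chrom=per_chrom,
        chain=chain,
        pmf=pmf,
        combine_calls=combine_calls,
    )


def results_table(results: list[ColocalizationResult], bh: bool = False) -> pd.DataFrame:
    """Stack result frames; optionally append Benjamini-Hochberg q-values.

    The q-value column is an explicitly-labelled convenience over the genome
    rows' enrichment p-values; per-chromosome rows get NaN.
    """
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    if bh:
        frame["bh_q_enrich"] = np.nan
        mask = (frame["chrom"] == "genome") & frame["p_enrich"].notna()
        if mask.any():
            frame.loc[mask, "bh_q_enrich"] = stats.false_discovery_control(
                frame.loc[mask, "p_enrich"].to_numpy(), method="bh"
            )
    return frame
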