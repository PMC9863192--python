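"""Neutrality-plot machinery: simple OLS and the mutation/selection partition.

A neutrality plot regresses GC12 (mean G+C at first and second codon
positions) on GC3 across species.  Because third positions are largely free
of protein-level constraint, a slope near 1 says directional mutation
pressure moves all positions together, while a slope near 0 says selection
holds the first two positions in place; the slope is therefore read as the
fractional contribution of mutation pressure (slope x 100 %) versus
selection ((1 - slope) x 100 %).

The same OLS routine serves the ENC-GC3 regression; significance is
reported through the F statistic of the slope, F = r^2 (n-2) / (1 - r^2)
on (1, n-2) degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codon_usage import GeneticCode, INVERTEBRATE_MITO, count_codons, gc_positions
from .mito_io import MitogenomeRecord, extract_partition

logger = logging.getLogger("mitocomp")


@dataclass(frozen=True)
class RegressionFit:
    n: int
    slope: float
    intercept: float
    r: float
    F_stat: float
    p_value: float
    residual_sd: float


def ols_fit(points: list[tuple[float, float]]) -> RegressionFit:
    """Closed-form simple least squares with slope F test.

    Requires n >= 3 and non-constant x.  ``p_value`` is the two-sided test
    of slope = 0 from the F(1, n-2) distribution (equivalently the squared-t
    test).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a slope test")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant: regression degenerate")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    sse = max(syy - slope * sxy, 0.0)
    residual_sd = math.sqrt(sse / (n - 2))
    if sse == 0.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = r * r * (n - 2) / (1 - r * r)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionFit(n, float(slope), intercept, float(r), float(f_stat),
                         p, residual_sd)


@dataclass(frozen=True)
class NeutralityPartition:
    mutation_pct: float
    selection_pct: float


def neutrality_partition(fit: RegressionFit) -> NeutralityPartition:
    """Mutation-pressure vs selection percentages from a GC12~GC3 slope.

    mutation = 100 x slope, selection = 100 - mutation (exact complement).
    Slopes outside [0, 1] are reported as-is with a warning — the standard
    interpretation no longer holds there.
    """
    slope = fit.slope
    if not 0.0 <= slope <= 1.0:
        logger.warning(
            "neutrality slope %.4f outside [0, 1]; percentage interpretation "
            "breaks down", slope,
        )
    mutation = 100.0 * slope
    return NeutralityPartition(mutation_pct=mutation, selection_pct=100.0 - mutation)


def neutrality_points(
    records: list[MitogenomeRecord], code: GeneticCode = INVERTEBRATE_MITO
) -> list[tuple[float, float]]:
    """One (GC3, GC12) point per genome, pooled over its concatenated PCGs.

    PCGs are taken on their coding strands; a record without protein-coding
    genes is skipped with a warning.
    """
    points = []
    for rec in records:
        cds = [seq for _, seq in extract_partition(rec, "PCG")]
        if not cds:
            logger.warning("%s: no PCGs, skipped from neutrality plot", rec.id)
            continue
        _, _, gc3, gc12 = gc_positions(count_codons(cds, code))
        points.append((gc3, gc12))
    return points


def enc_gc3_points(
    records: list[MitogenomeRecord], code: GeneticCode = INVERTEBRATE_MITO
) -> list[tuple[float, float]]:
    """One (GC3, ENC) point per genome for the ENC plot."""
    from .codon_usage import enc as _enc

    points = []
    for rec in records:
        cds = [seq for _, seq in extract_partition(rec, "PCG")]
        if not cds:
            logger.warning("%s: no PCGs, skipped from ENC plot", rec.id)
            continue
        summary = count_codons(cds, code)
        _, _, gc3, _ = gc_positions(summary)
        points.append((gc3, _enc(summary)))
    return points


__all__ = [
    "RegressionFit",
    "NeutralityPartition",
    "ols_fit",
    "neutrality_partition",
    "neutrality_points",
    "enc_gc3_points",
]
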