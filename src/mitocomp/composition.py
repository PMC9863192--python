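"""Nucleotide composition, A+T content and strand skews per genome partition.

All metrics are computed on the majority (J) strand: whole-genome values on
the genome sequence itself, partition values on the concatenation of the
partition's features as they lie on the majority strand (minus-strand genes
are *not* reverse-complemented here — strand asymmetry is the point of the
skew statistics).  ``N`` bases are excluded from both numerator and
denominator.

Skews follow the standard Perna-Kocher definitions:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

Group differences (e.g. one insect family against the rest of an order) are
tested with a two-sided Mann-Whitney U test by default, with Welch's t-test
available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mito_io import MitogenomeRecord, PARTITIONS, revcomp

logger = logging.getLogger("mitocomp")


@dataclass(frozen=True)
class CompositionSummary:
    record_id: str
    partition: str
    length_bp: int
    frac_A: float
    frac_T: float
    frac_G: float
    frac_C: float
    at_content: float
    at_skew: float  # NaN when A+T == 0
    gc_skew: float  # NaN when G+C == 0


def at_skew(seq: str) -> float:
    """(A - T)/(A + T); NaN when the sequence has no A or T after N-removal."""
    a, t = seq.count("A"), seq.count("T")
    return (a - t) / (a + t) if a + t else math.nan


def gc_skew(seq: str) -> float:
    """(G - C)/(G + C); NaN when the sequence has no G or C after N-removal."""
    g, c = seq.count("G"), seq.count("C")
    return (g - c) / (g + c) if g + c else math.nan


def _partition_sequence(record: MitogenomeRecord, partition: str) -> str:
    """Concatenated partition sequence as stored on the majority strand."""
    if partition == "whole":
        return record.sequence
    parts = []
    for f in record.features_of_kind(partition):
        if f.wraps_origin:
            parts.append(record.sequence[f.start - 1:] + record.sequence[: f.end])
        else:
            parts.append(record.sequence[f.start - 1: f.end])
    return "".join(parts)


def composition_summary(record: MitogenomeRecord, partition: str) -> CompositionSummary:
    """Base fractions, A+T content and skews of one partition of one genome.

    An empty partition yields length 0 with all metrics NaN.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    seq = _partition_sequence(record, partition)
    counts = {b: seq.count(b) for b in "ATGC"}
    n = sum(counts.values())
    if n == 0:
        nan = math.nan
        return CompositionSummary(record.id, partition, len(seq),
                                  nan, nan, nan, nan, nan, nan, nan)
    a, t, g, c = (counts[b] / n for b in "ATGC")
    return CompositionSummary(
        record_id=record.id,
        partition=partition,
        length_bp=len(seq),
        frac_A=a, frac_T=t, frac_G=g, frac_C=c,
        at_content=a + t,
        at_skew=at_skew(seq),
        gc_skew=gc_skew(seq),
    )


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    tier: str  # "***" (p<0.01), "**" (p<0.05), "ns"
    test: str
    reliable: bool  # False for singleton groups


def _tier(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    return "ns"


def group_compare(
    group_a: list[CompositionSummary] | list[float],
    group_b: list[CompositionSummary] | list[float],
    metric: str = "at_content",
    test: str = "mannwhitney",
) -> GroupComparison:
    """Two-sided two-sample test of one composition metric between groups.

    Accepts either :class:`CompositionSummary` lists (``metric`` selects the
    field) or plain float lists.  ``test`` is ``"mannwhitney"`` (default,
    rank-based; robust at small n) or ``"ttest"`` (Welch).  Singleton groups
    are flagged unreliable.
    """
    def values(g):
        return np.asarray(
            [getattr(x, metric) if isinstance(x, CompositionSummary) else float(x)
             for x in g],
            dtype=float,
        )

    xa, xb = values(group_a), values(group_b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([xa, xb])
    if np.ptp(pooled) == 0.0:
        # all observations identical: no evidence of any difference
        stat = xa.size * xb.size / 2.0 if test == "mannwhitney" else 0.0
        p = 1.0
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    elif test == "ttest":
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    reliable = xa.size > 1 and xb.size > 1
    if not reliable:
        logger.warning("group_compare: singleton group, p-value unreliable")
    return GroupComparison(
        metric=metric,
        n_a=int(xa.size), n_b=int(xb.size),
        median_a=float(np.median(xa)), median_b=float(np.median(xb)),
        statistic=float(stat), p_value=float(p),
        tier=_tier(float(p)), test=test, reliable=reliable,
    )


__all__ = [
    "CompositionSummary",
    "GroupComparison",
    "composition_summary",
    "at_skew",
    "gc_skew",
    "group_compare",
    "revcomp",
]
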