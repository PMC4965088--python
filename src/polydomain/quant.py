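"""Broad-domain segmentation and ChIP/RT-qPCR arithmetic.

Covers the region-level quantification conventions used around a broad
H3K27me3 domain: segmenting the domain from a coverage track, converting
qPCR Ct values to percent-of-input enrichment with an explicit
input-fraction dilution correction, expressing enrichment as fold over a
background region, comparing conditions with a t-test, and ddCt-style
relative expression against a reference transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import CoverageTrack, GenomicInterval

__all__ = [
    "DomainCall",
    "RegionQuant",
    "CtRecord",
    "TTestResult",
    "call_broad_domains",
    "percent_input",
    "fold_over_background",
    "compare_conditions",
    "relative_expression",
    "summarize_region",
]


@dataclass
class DomainCall:
    interval: GenomicInterval
    mean_enrichment: float  # mean fold over background across the domain
    n_bins: int


@dataclass
class RegionQuant:
    """Replicate-level fold enrichments for one region, with summary stats."""

    region: GenomicInterval | str
    folds: np.ndarray  # one fold-enrichment value per replicate
    mean: float
    sem: float
    p_value: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class CtRecord:
    """One ChIP-qPCR measurement: ChIP and input Ct plus the input fraction
    (the proportion of chromatin saved for the input reaction)."""

    target: str
    ct_chip: float
    ct_input: float
    input_fraction: float = 0.033

    def __post_init__(self) -> None:
        for name, v in (("ct_chip", self.ct_chip), ("ct_input", self.ct_input)):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not 0 < self.input_fraction <= 1:
            raise ValueError(
                f"input_fraction must lie in (0, 1], got {self.input_fraction}"
            )


def call_broad_domains(
    track: CoverageTrack,
    background: float,
    enrich_threshold: float = 3.0,
    max_gap: int = 2000,
) -> list[DomainCall]:
    """Segment broad enriched domains from a coverage track.

    Bins at or above ``enrich_threshold`` times ``background`` are merged
    into one domain when separated by at most ``max_gap`` bp; each domain
    reports its span and mean enrichment (mean signal / background) over
    its above-threshold bins.
    """
    if background <= 0:
        raise ValueError(f"background must be positive, got {background}")
    if enrich_threshold <= 1:
        raise ValueError("enrich_threshold must exceed 1 (fold over background)")
    hot = np.flatnonzero(track.values >= enrich_threshold * background)
    domains: list[DomainCall] = []
    if hot.size == 0:
        return domains
    groups: list[list[int]] = [[int(hot[0])]]
    for idx in hot[1:]:
        gap_bp = (int(idx) - groups[-1][-1] - 1) * track.bin_size
        if gap_bp <= max_gap:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    for grp in groups:
        lo, hi = grp[0], grp[-1] + 1
        iv = GenomicInterval(track.chrom, lo * track.bin_size, hi * track.bin_size)
        mean_enr = float(track.values[np.array(grp)].mean() / background)
        domains.append(DomainCall(interval=iv, mean_enrichment=mean_enr,
                                  n_bins=len(grp)))
    return domains


def percent_input(rec: CtRecord) -> float:
    """ChIP recovery relative to total input.

    The input Ct is first shifted down by log2(1 / input_fraction) to
    represent 100% of the chromatin; the result is
    2**(Ct_input_adjusted - Ct_chip), so 1.0 means the ChIP recovered the
    whole input.  Invariant to adding a constant to both Ct values.
    """
    adj = rec.ct_input - math.log2(1.0 / rec.input_fraction)
    return 2.0 ** (adj - rec.ct_chip)


def fold_over_background(target: float, background: float) -> float:
    """Ratio of a target-region enrichment to a background-region one."""
    if background <= 0:
        raise ValueError(f"background enrichment must be positive, got {background}")
    return target / background


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool  # p <= 0.05


def compare_conditions(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sample t-test between replicate fold-enrichment groups.

    Welch (unequal variance) by default; ``equal_var=True`` gives the
    pooled-variance Student form.  Two-sided; the significance flag marks
    p <= alpha (0.05 by convention).  Swapping groups negates t and leaves
    p unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p), significant=bool(p <= alpha))


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Transcript level relative to a reference gene: 2**(Ct_ref - Ct_target)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_reference - ct_target)


def summarize_region(
    region: GenomicInterval | str,
    replicate_folds: Sequence[float],
    control_folds: Sequence[float] | None = None,
) -> RegionQuant:
    """Mean +/- SEM over replicate folds, optionally with a Welch t-test
    against a control condition."""
    folds = np.asarray(replicate_folds, dtype=float)
    if folds.size < 1:
        raise ValueError("need at least one replicate fold")
    sem = float(folds.std(ddof=1) / math.sqrt(folds.size)) if folds.size > 1 else 0.0
    p = sig = None
    if control_folds is not None:
        res = compare_conditions(folds, control_folds)
        p, sig = res.p, res.significant
    return RegionQuant(
        region=region,
        folds=folds,
        mean=float(folds.mean()),
        sem=sem,
        p_value=p,
        significant=sig,
    )
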