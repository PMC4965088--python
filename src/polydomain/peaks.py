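"""Enriched-region detection, sub-peak splitting and strength ranking.

The caller is a fixed-background Poisson scan: every bin is tested against
a single genome-wide background rate (no local lambda), significant bins
are merged into peaks, and each peak carries the summit position, summit
height and its best bin p-value.  Called peaks can then be split at deep
valleys into sub-peaks and ranked into strong / weak / null classes by
descending summit height.

The three-tier classification is rank-based: after discarding peaks below
a retention height floor, the top ``strong_frac`` of retained peaks are
"strong", the next ``weak_frac`` are "weak" and the remainder "null".  The
empirical heights at the class boundaries are reported so users can check
that, on data resembling larval Pho ChIP, they land near 400 and 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .core_io import CoverageTrack, GenomicInterval

__all__ = [
    "Peak",
    "ClassificationResult",
    "poisson_upper_tail",
    "call_enriched_regions",
    "split_peak",
    "classify_peaks",
    "colocalize",
]

CATEGORIES = ("strong", "weak", "null", "unretained", "unclassified")


@dataclass
class Peak:
    """An enriched region with summit, height and classification state."""

    interval: GenomicInterval
    summit: int
    height: float
    p_value: float = math.nan
    category: str = "unclassified"
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval {self.interval}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def poisson_upper_tail(k: np.ndarray | float, lam: float) -> np.ndarray | float:
    """P(X >= k) for X ~ Poisson(lam).

    Uses the regularized incomplete-gamma identity
    ``P(X >= k) = P(k, lam)`` (``scipy.special.gammainc``), which is exact
    for integer k and extends continuously to fractional observed counts.
    ``k <= 0`` returns 1.
    """
    if lam <= 0:
        raise ValueError(f"background rate must be positive, got {lam}")
    k = np.asarray(k, dtype=float)
    out = np.ones_like(k)
    pos = k > 0
    out[pos] = special.gammainc(k[pos], lam)
    if out.ndim == 0:
        return float(out)
    return out


def call_enriched_regions(
    track: CoverageTrack,
    background_rate: float,
    p_cutoff: float = 1e-5,
    min_gap: int = 1,
) -> list[Peak]:
    """Fixed-background Poisson peak calling on a raw-count track.

    Bins whose Poisson upper-tail probability against ``background_rate``
    (expected reads per bin) falls below ``p_cutoff`` are flagged; flagged
    bins separated by less than ``min_gap`` bp of unflagged territory merge
    into one peak.  Summit is the maximum-signal bin (leftmost on ties);
    the peak p-value is the best bin p-value.
    """
    if background_rate <= 0:
        raise ValueError(f"background rate must be positive, got {background_rate}")
    vals = track.values
    pvals = np.asarray(poisson_upper_tail(vals, background_rate))
    flagged = np.flatnonzero(pvals < p_cutoff)
    peaks: list[Peak] = []
    if flagged.size == 0:
        return peaks
    # group flagged bins: gap in bp between consecutive flagged bins
    groups: list[list[int]] = [[int(flagged[0])]]
    for idx in flagged[1:]:
        gap_bp = (int(idx) - groups[-1][-1] - 1) * track.bin_size
        if gap_bp < min_gap:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    for grp in groups:
        lo, hi = grp[0], grp[-1] + 1
        seg = vals[lo:hi]
        best = lo + int(np.argmax(seg))
        iv = GenomicInterval(track.chrom, lo * track.bin_size, hi * track.bin_size)
        peaks.append(
            Peak(
                interval=iv,
                summit=best * track.bin_size + track.bin_size // 2,
                height=float(vals[best]),
                p_value=float(pvals[lo:hi].min()),
            )
        )
    return peaks


def _local_maxima(v: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus contribute their leftmost index,
    array boundaries count as descending."""
    n = v.size
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def split_peak(
    peak: Peak,
    track: CoverageTrack,
    valley_fraction: float = 0.5,
    min_summit_height: float = 0.0,
) -> list[Peak]:
    """Split a called peak at deep valleys into sub-peaks.

    Local maxima at or above ``min_summit_height`` are candidate summits.
    Two adjacent summits belong to distinct sub-peaks iff the minimum
    signal between them drops below ``valley_fraction`` times the lower of
    the two summit heights; otherwise the lower summit is absorbed.
    Candidates are resolved in descending height order (leftmost first on
    ties), so the outcome is deterministic.  Sub-peak boundaries sit at the
    (leftmost) valley minima and the sub-peaks tile the parent interval.
    """
    if not 0 < valley_fraction < 1:
        raise ValueError("valley_fraction must be in (0, 1)")
    lo, hi = track.slice_bins(peak.interval)
    v = track.values[lo:hi]
    if v.size == 0 or not np.any(v > 0):
        raise ValueError(f"no signal within peak {peak.interval}")
    candidates = [i for i in _local_maxima(v) if v[i] >= min_summit_height]
    if len(candidates) <= 1:
        return [replace(peak)]
    order = sorted(candidates, key=lambda i: (-v[i], i))
    accepted: list[int] = [order[0]]
    for cand in order[1:]:
        h = v[cand]
        separated = True
        for neigh in _flanking(accepted, cand):
            a, b = min(cand, neigh), max(cand, neigh)
            valley = v[a : b + 1].min()
            if valley >= valley_fraction * h:  # h <= v[neigh] by order
                separated = False
                break
        if separated:
            accepted.append(cand)
            accepted.sort()
    if len(accepted) == 1:
        return [replace(peak)]
    # boundaries at leftmost valley minimum between adjacent accepted summits
    bounds = [0]
    for s1, s2 in zip(accepted, accepted[1:]):
        seg = v[s1 : s2 + 1]
        bounds.append(s1 + int(np.argmin(seg)))
    bounds.append(v.size)
    subs = []
    for k, summ in enumerate(accepted):
        b0, b1 = bounds[k], bounds[k + 1]
        start = peak.interval.start if k == 0 else (lo + b0) * track.bin_size
        end = peak.interval.end if k == len(accepted) - 1 else (lo + b1) * track.bin_size
        iv = GenomicInterval(track.chrom, start, end)
        summit_bp = (lo + summ) * track.bin_size + track.bin_size // 2
        summit_bp = min(max(summit_bp, iv.start), iv.end - 1)
        subs.append(
            Peak(interval=iv, summit=summit_bp, height=float(v[summ]),
                 p_value=peak.p_value)
        )
    return subs


def _flanking(sorted_accepted: list[int], cand: int) -> list[int]:
    """Nearest already-accepted summits left and right of `cand`."""
    left = [i for i in sorted_accepted if i < cand]
    right = [i for i in sorted_accepted if i > cand]
    out = []
    if left:
        out.append(left[-1])
    if right:
        out.append(right[0])
    return out


@dataclass
class ClassificationResult:
    """Classified peaks plus the empirical class-boundary heights."""

    peaks: list[Peak]
    n_retained: int
    n_strong: int
    n_weak: int
    n_null: int
    strong_boundary_height: float | None  # height of the lowest strong peak
    weak_boundary_height: float | None  # height of the lowest weak peak


def classify_peaks(
    peaks: list[Peak],
    retention_min_height: float = 50.0,
    strong_frac: float = 0.10,
    weak_frac: float = 0.35,
) -> ClassificationResult:
    """Rank retained peaks by height into strong / weak / null tiers.

    Peaks below ``retention_min_height`` are marked ``unretained``.  The
    remaining N peaks are ranked by descending height (ties: leftmost
    coordinate first); the first ``ceil(strong_frac * N)`` are strong, the
    next ``ceil(weak_frac * N)`` weak and the rest null.  Returned peaks
    keep input order; ranks are 1-based among retained peaks.
    """
    if strong_frac < 0 or weak_frac < 0 or strong_frac + weak_frac > 1:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    out = [replace(p) for p in peaks]
    retained = [p for p in out if p.height >= retention_min_height]
    for p in out:
        if p.height < retention_min_height:
            p.category = "unretained"
            p.rank = None
    retained.sort(key=lambda p: (-p.height, p.interval.chrom, p.interval.start))
    n = len(retained)
    n_strong = min(math.ceil(strong_frac * n), n)
    n_weak = min(math.ceil(weak_frac * n), n - n_strong)
    for r, p in enumerate(retained, start=1):
        p.rank = r
        if r <= n_strong:
            p.category = "strong"
        elif r <= n_strong + n_weak:
            p.category = "weak"
        else:
            p.category = "null"
    return ClassificationResult(
        peaks=out,
        n_retained=n,
        n_strong=n_strong,
        n_weak=n_weak,
        n_null=n - n_strong - n_weak,
        strong_boundary_height=retained[n_strong - 1].height if n_strong else None,
        weak_boundary_height=(
            retained[n_strong + n_weak - 1].height if n_weak else None
        ),
    )


def colocalize(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    max_summit_distance: int = 1000,
) -> list[tuple[Peak, Peak]]:
    """Greedy nearest-summit matching of two peak lists.

    Pairs (a, b) on the same chromosome with summit distance at most
    ``max_summit_distance`` are matched closest-first (ties: leftmost
    summit in list a, then in list b); each peak joins at most one pair.
    """
    cands = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.interval.chrom != b.interval.chrom:
                continue
            d = abs(a.summit - b.summit)
            if d <= max_summit_distance:
                cands.append((d, a.summit, b.summit, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i], peaks_b[j]))
    return pairs


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """BED6+3: name=category, score=height, extra: summit, p_value, rank."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.category,
                        f"{p.height:g}",
                        p.interval.strand,
                        str(p.summit),
                        f"{p.p_value:g}",
                        "" if p.rank is None else str(p.rank),
                    ]
                )
                + "\n"
            )


def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            peaks.append(
                Peak(
                    interval=iv,
                    summit=int(f[6]),
                    height=float(f[4]),
                    p_value=float(f[7]),
                    category=f[3],
                    rank=int(f[8]) if len(f) > 8 and f[8] else None,
                )
            )
    return peaks
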