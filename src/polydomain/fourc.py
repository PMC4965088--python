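"""4C-seq viewpoint interaction calling.

The pipeline mirrors the standard domainogram-style analysis for a single
bait (viewpoint): per-restriction-fragment read counts are variance
stabilized, a smooth distance-decay background is fit by loess with the
bait's neighbourhood excluded, enrichment p-values are computed from
robust-z residuals per replicate, Benjamini-Hochberg adjusted within each
replicate, and a fragment is called a bona-fide interaction when its raw
p-value beats ``p_thresh`` in *every* replicate and its FDR beats
``fdr_thresh`` in at least one.

The variance-stabilizing transform is the analytic one for a
negative-binomial mean-variance relation v = mu + alpha * mu**2:

    g(n) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * n))

which is the closed form of integral_0^n dmu / sqrt(mu + alpha mu^2).
Since the downstream z-statistic is scale-free, only the flattening of the
mean-variance relation matters, not the transform's absolute scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval

__all__ = [
    "RestrictionFragment",
    "FourCProfile",
    "digest_sequence",
    "estimate_dispersion",
    "vst_transform",
    "loess_smooth",
    "fit_background",
    "residual_pvalues",
    "bh_adjust",
    "call_interactions",
    "analyze_profile",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class RestrictionFragment:
    """One unit of the in-silico digest; fragments tile the chromosome."""

    interval: GenomicInterval
    index: int


def digest_sequence(
    seq: str,
    site: str,
    chrom: str = "chr",
    cut_offset: int = 0,
) -> list[RestrictionFragment]:
    """In-silico restriction digest of ``seq`` at every occurrence of
    ``site`` (overlapping occurrences included).

    The cut is placed ``cut_offset`` bases into the recognition site
    (default 0 = at the site start; EcoRI's G^AATTC corresponds to
    ``cut_offset=1``).  Fragments tile ``[0, len(seq))``; zero-length
    fragments from coincident cuts are suppressed.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(
            f"ambiguous or invalid letters in recognition site {site!r}; "
            "only unambiguous ACGT sites are supported"
        )
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the recognition site")
    seq = seq.upper()
    cuts = set()
    start = seq.find(site)
    while start != -1:
        cuts.add(start + cut_offset)
        start = seq.find(site, start + 1)
    bounds = sorted(c for c in cuts if 0 < c < len(seq))
    edges = [0, *bounds, len(seq)]
    frags = []
    for i, (a, b) in enumerate(zip(edges, edges[1:])):
        if b > a:
            frags.append(
                RestrictionFragment(GenomicInterval(chrom, a, b), index=len(frags))
            )
    return frags


def estimate_dispersion(counts: np.ndarray, fallback: float = 0.1) -> float:
    """Method-of-moments NB dispersion from a fragments x replicates matrix.

    Pools the per-fragment excess variance: alpha = sum(v - m) / sum(m^2)
    with per-fragment sample mean m and variance v.  Falls back to
    ``fallback`` when fewer than 2 replicates or no excess variance.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        return fallback
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    denom = float(np.sum(m**2))
    if denom <= 0:
        return fallback
    alpha = float(np.sum(v - m)) / denom
    return alpha if alpha > 0 else fallback


def vst_transform(counts: np.ndarray, dispersion: float = 0.1) -> np.ndarray:
    """Variance-stabilizing transform for NB counts (see module docstring).

    Strictly increasing with g(0) = 0; for alpha -> 0 it approaches the
    Poisson stabilizer 2*sqrt(n).
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return (2.0 / math.sqrt(dispersion)) * np.arcsinh(np.sqrt(dispersion * counts))


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_pred: np.ndarray,
    span: float = 0.2,
) -> np.ndarray:
    """Local linear regression with tricube weights.

    For each prediction point the ``ceil(span * n)`` nearest fitting points
    (contiguous in x, found by a sliding window over the sorted abscissae)
    get tricube weights w(u) = (1 - |u|^3)^3, u = distance / max distance,
    and a weighted degree-1 fit is evaluated at the point.  Exact on data
    that are globally linear in x.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    k = max(2, math.ceil(span * n))
    k = min(k, n)
    out = np.empty(np.asarray(x_pred).size, dtype=float)
    pred = np.asarray(x_pred, dtype=float)
    pred_order = np.argsort(pred, kind="stable")
    lo = 0
    for rank in pred_order:
        xi = pred[rank]
        # slide window of width k to the k nearest neighbours of xi
        while lo + k < n and xs[lo + k] - xi < xi - xs[lo]:
            lo += 1
        xw = xs[lo : lo + k]
        yw = ys[lo : lo + k]
        d = np.abs(xw - xi)
        dmax = d.max()
        if dmax == 0:
            out[rank] = yw.mean()
            continue
        u = d / dmax
        w = (1.0 - u**3) ** 3
        sw = w.sum()
        if sw <= 0:
            out[rank] = yw.mean()
            continue
        xm = np.dot(w, xw) / sw
        ym = np.dot(w, yw) / sw
        dxw = xw - xm
        sxx = np.dot(w, dxw * dxw)
        if sxx <= 1e-12 * max(1.0, xm * xm):
            out[rank] = ym
            continue
        slope = np.dot(w, dxw * (yw - ym)) / sxx
        out[rank] = ym + slope * (xi - xm)
    return out


def fit_background(
    fragments: list[RestrictionFragment],
    values: np.ndarray,
    exclusion_window: GenomicInterval | None,
    span: float = 0.2,
    min_points: int = 10,
) -> np.ndarray:
    """Loess background expectation over fragment midpoints.

    Fragments overlapping ``exclusion_window`` (the bait neighbourhood) are
    excluded from the fit but still receive predicted values, so residuals
    are defined everywhere.
    """
    values = np.asarray(values, dtype=float)
    if len(fragments) != values.size:
        raise ValueError("fragments and values must have equal length")
    mids = np.array([f.interval.midpoint() for f in fragments])
    if exclusion_window is None:
        fit_mask = np.ones(len(fragments), dtype=bool)
    else:
        fit_mask = np.array(
            [not f.interval.overlaps(exclusion_window) for f in fragments]
        )
    if fit_mask.sum() < min_points:
        raise ValueError(
            f"only {int(fit_mask.sum())} fragments outside the exclusion "
            f"window; need at least {min_points} to fit a background"
        )
    return loess_smooth(mids[fit_mask], values[fit_mask], mids, span=span)


def residual_pvalues(values: np.ndarray, fit: np.ndarray) -> np.ndarray:
    """One-sided (enrichment) p-values from robust-z residuals.

    Residuals r = value - fit are standardized by the MAD-based robust
    scale s = 1.4826 * median(|r - median(r)|); p = upper-tail standard
    normal probability of z = r / s.  Invariant to affine rescaling of the
    transformed values.
    """
    values = np.asarray(values, dtype=float)
    fit = np.asarray(fit, dtype=float)
    if values.shape != fit.shape:
        raise ValueError("values and fit must have the same shape")
    if values.size < 3:
        raise ValueError("need at least 3 fragments for residual p-values")
    r = values - fit
    s = 1.4826 * np.median(np.abs(r - np.median(r)))
    if s == 0:
        raise ValueError("all residuals identical; robust scale is zero")
    z = r / s
    p = stats.norm.sf(z)
    return np.clip(p, np.nextafter(0, 1), np.nextafter(1, 0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{k >= i} p_(k) * n / k over the ascending order statistics,
    clipped at 1; order-preserving, q >= p elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class FourCProfile:
    """Per-fragment 4C counts and derived statistics around one bait.

    ``counts`` is a fragments x replicates integer matrix; the transformed
    values, background fit, p and q matrices share that shape once
    :func:`analyze_profile` has run.
    """

    bait: GenomicInterval
    exclusion_window: GenomicInterval
    fragments: list[RestrictionFragment]
    counts: np.ndarray
    dispersion: float | None = None
    transformed: np.ndarray | None = None
    fit: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a fragments x replicates matrix")
        if self.counts.shape[0] != len(self.fragments):
            raise ValueError("counts rows must match fragment count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    def excluded_mask(self) -> np.ndarray:
        return np.array(
            [f.interval.overlaps(self.exclusion_window) for f in self.fragments]
        )


def call_interactions(
    profile: FourCProfile,
    p_thresh: float = 0.01,
    fdr_thresh: float = 0.1,
) -> FourCProfile:
    """Replicate-consensus interaction call.

    A fragment is significant iff its raw p-value is below ``p_thresh`` in
    every replicate AND its BH-adjusted value is below ``fdr_thresh`` in at
    least one replicate.  Fragments overlapping the bait-exclusion window
    are never called.
    """
    if profile.p is None or profile.q is None:
        raise ValueError("profile must carry p and q; run analyze_profile first")
    if profile.n_replicates < 2:
        raise ValueError("replicate-consensus calling needs >= 2 replicates")
    sig = np.all(profile.p < p_thresh, axis=1) & np.any(
        profile.q < fdr_thresh, axis=1
    )
    sig &= ~profile.excluded_mask()
    profile.significant = sig
    return profile


def analyze_profile(
    profile: FourCProfile,
    dispersion: float | None = None,
    span: float = 0.2,
    p_thresh: float = 0.01,
    fdr_thresh: float = 0.1,
) -> FourCProfile:
    """Run the full per-replicate 4C pipeline in place.

    VST -> loess background (bait window excluded from the fit) -> robust-z
    residual p-values -> per-replicate BH adjustment across all fragments
    of the bait chromosome -> replicate-consensus call.
    """
    if profile.n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    if dispersion is None:
        dispersion = estimate_dispersion(profile.counts)
    profile.dispersion = dispersion
    n_frag, n_rep = profile.counts.shape
    profile.transformed = np.empty((n_frag, n_rep))
    profile.fit = np.empty((n_frag, n_rep))
    profile.p = np.empty((n_frag, n_rep))
    profile.q = np.empty((n_frag, n_rep))
    for r in range(n_rep):
        t = vst_transform(profile.counts[:, r], dispersion)
        f = fit_background(
            profile.fragments, t, profile.exclusion_window, span=span
        )
        profile.transformed[:, r] = t
        profile.fit[:, r] = f
        profile.p[:, r] = residual_pvalues(t, f)
        profile.q[:, r] = bh_adjust(profile.p[:, r])
    return call_interactions(profile, p_thresh=p_thresh, fdr_thresh=fdr_thresh)


def write_counts_tsv(profile: FourCProfile, path) -> None:
    """Fragment counts as TSV: chrom, start, end, count_rep1, count_rep2, ..."""
    df = pd.DataFrame(
        {
            "chrom": [f.interval.chrom for f in profile.fragments],
            "start": [f.interval.start for f in profile.fragments],
            "end": [f.interval.end for f in profile.fragments],
        }
    )
    for r in range(profile.n_replicates):
        df[f"count_rep{r + 1}"] = profile.counts[:, r]
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path,
    bait: GenomicInterval,
    exclusion_window: GenomicInterval,
) -> FourCProfile:
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("count_rep")]
    if not count_cols:
        raise ValueError("no count_rep columns in counts TSV")
    frags = [
        RestrictionFragment(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end)), i
        )
        for i, row in enumerate(df.itertuples())
    ]
    return FourCProfile(
        bait=bait,
        exclusion_window=exclusion_window,
        fragments=frags,
        counts=df[count_cols].to_numpy(),
    )


def write_calls_bed(profile: FourCProfile, path) -> None:
    """Significant fragments as BED, best q-value in the score column."""
    if profile.significant is None:
        raise ValueError("run analyze_profile / call_interactions first")
    with open(path, "w") as fh:
        for frag, sig in zip(profile.fragments, profile.significant):
            if not sig:
                continue
            qbest = float(profile.q[frag.index].min())
            fh.write(
                f"{frag.interval.chrom}\t{frag.interval.start}\t"
                f"{frag.interval.end}\tinteraction\t{qbest:.4g}\t.\n"
            )
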