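"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator formalizes a cooperative-PRE picture of a Polycomb domain:
H3K27me3 nucleates at a handful of strong PREs and many weak ones, spreads
with an exponentially decaying kernel, and is attenuated by insulators; a
4C viewpoint sees a power-law contact decay with planted interaction
enrichments; Pho-like peak heights come in a strong (>= 400) / weak
(100-400) / sub-threshold mixture.  All noise is negative-binomial (counts)
or Gaussian (qPCR cycles), every output is a pure function of the
:class:`SimConfig` (seed included), and each dataset ships a
:class:`SimTruth` sufficient to recompute its expected means exactly.

This is a generator for testing recovery, not a biophysical model of
chromatin: parameters live in the config, and defaults emulate the scale
of a ~113 kb domain with four strong and ten weak nucleation sites.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, GenomicInterval, write_bedgraph, write_fasta
from .fourc import FourCProfile, RestrictionFragment, write_counts_tsv
from .peaks import Peak
from .quant import CtRecord

__all__ = [
    "PreSite",
    "PlantedInteraction",
    "SimConfig",
    "SimTruth",
    "default_pre_sites",
    "generate_genome",
    "expected_k27_mean",
    "simulate_k27_coverage",
    "simulate_pho_peak_heights",
    "simulate_4c",
    "simulate_qpcr",
    "simulate_all",
]


@dataclass(frozen=True)
class PreSite:
    """A nucleation site: genomic position, strength (signal units added at
    the site itself) and strong/weak class."""

    position: int
    strength: float
    klass: str  # "strong" | "weak"
    has_gaga: bool = True

    def __post_init__(self) -> None:
        if self.klass not in {"strong", "weak"}:
            raise ValueError(f"PRE class must be strong or weak, got {self.klass!r}")
        if self.strength <= 0:
            raise ValueError("PRE strength must be positive")


@dataclass(frozen=True)
class PlantedInteraction:
    """A ground-truth 4C contact: fragment index and fold enrichment over
    the distance-decay background."""

    fragment_index: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted fold must exceed 1")


def default_pre_sites() -> list[PreSite]:
    """Four strong and ten weak PREs across a ~113 kb domain.

    Strong strengths put peak signal well above 400; weak strengths sit in
    the 100-400 band.  Two weak sites lack GAGA motifs, mirroring the
    observation that some sub-peaks carry no GAGA site.
    """
    strong = [
        PreSite(60_000, 620.0, "strong"),
        PreSite(66_000, 540.0, "strong"),
        PreSite(112_000, 480.0, "strong"),
        PreSite(114_500, 430.0, "strong"),
    ]
    weak_positions = [48_000, 72_000, 80_000, 87_000, 94_000,
                      101_000, 122_000, 131_000, 140_000, 150_000]
    weak_strengths = [140.0, 180.0, 220.0, 160.0, 260.0,
                      300.0, 240.0, 200.0, 170.0, 150.0]
    weak = [
        PreSite(p, s, "weak", has_gaga=(i % 5 not in (1, 3)))
        for i, (p, s) in enumerate(zip(weak_positions, weak_strengths))
    ]
    return strong + weak


@dataclass
class SimConfig:
    """All generator parameters; every output is a pure function of this."""

    genome_length: int = 200_000
    chrom: str = "sim2R"
    bin_size: int = 100
    pres: list[PreSite] = field(default_factory=default_pre_sites)
    insulator_positions: list[int] = field(default_factory=list)
    insulator_beta: float = 0.5  # multiplicative attenuation per insulator
    spread_length: float = 5_000.0  # exponential kernel scale, bp
    background: float = 5.0  # expected reads per bin away from PREs
    nb_dispersion: float = 0.1
    # 4C side
    bait_position: int = 113_000
    fragment_size: int = 400
    n_fragments: int = 500
    decay_gamma: float = 1.0
    decay_d0: float = 1.0  # fragment units
    fourc_depth: float = 100_000.0  # expected reads per replicate
    exclusion_halfwidth: int = 3_000  # 6 kb window centered on the bait
    planted: list[PlantedInteraction] = field(default_factory=list)
    n_replicates: int = 2
    # qPCR side
    qpcr_noise_sd: float = 0.15  # Gaussian Ct noise, cycles
    input_fraction: float = 0.033
    ct_input: float = 20.0
    background_percent_input: float = 0.005  # percent-input at background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if not 0 < self.insulator_beta <= 1:
            raise ValueError("insulator_beta must lie in (0, 1]")
        for v, name in [
            (self.spread_length, "spread_length"),
            (self.background, "background"),
            (self.nb_dispersion, "nb_dispersion"),
            (self.fourc_depth, "fourc_depth"),
            (self.decay_gamma, "decay_gamma"),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for pre in self.pres:
            if not 0 <= pre.position < self.genome_length:
                raise ValueError(f"PRE at {pre.position} outside genome")
        if not 0 <= self.bait_position < self.n_fragments * self.fragment_size:
            raise ValueError("bait_position outside the fragment map")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


@dataclass
class SimTruth:
    """Realized ground truth for one generated dataset."""

    seed: int
    pres: list[PreSite] = field(default_factory=list)
    insulator_positions: list[int] = field(default_factory=list)
    planted_interactions: list[PlantedInteraction] = field(default_factory=list)
    mean_curve: np.ndarray | None = None  # expected signal per bin / fragment
    planted_motifs: dict[int, dict[str, int]] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _rng(cfg: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), *tags]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mean + alpha * mean**2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# genome + planted motif clusters

_MOTIF_CLUSTERS = {
    # plantings per PRE class; weak sites flagged has_gaga=False drop GAGAG
    "strong": {"GAGAG": 3, "GCCAT": 3, "GTGT": 2},
    "weak": {"GAGAG": 1, "GCCAT": 2, "GTGT": 1},
}


def generate_genome(cfg: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Random ACGT genome with a motif cluster planted at every PRE.

    Planted counts are additive to chance background occurrences, so a
    census over a PRE window recovers *at least* the planted counts.
    """
    rng = _rng(cfg, 1)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.genome_length)
    truth = SimTruth(seed=cfg.seed, pres=list(cfg.pres))
    for pre in cfg.pres:
        plan = dict(_MOTIF_CLUSTERS[pre.klass])
        if not pre.has_gaga:
            plan.pop("GAGAG", None)
        offset = max(pre.position - 150, 0)
        planted: dict[str, int] = {}
        for motif, count in plan.items():
            for _ in range(count):
                if offset + len(motif) > cfg.genome_length:
                    break
                seq[offset : offset + len(motif)] = np.frombuffer(
                    motif.encode(), dtype="S1"
                )
                planted[motif] = planted.get(motif, 0) + 1
                offset += len(motif) + 20  # spacer keeps plantings disjoint
        truth.planted_motifs[pre.position] = planted
    genome = {cfg.chrom: seq.tobytes().decode()}
    return genome, truth


# ---------------------------------------------------------------------------
# H3K27me3 coverage

def _check_deletions(cfg: SimConfig, deletions: Sequence[GenomicInterval]) -> None:
    dels = sorted(deletions, key=lambda d: d.start)
    for d in dels:
        if d.chrom != cfg.chrom:
            raise ValueError(f"deletion {d} on unknown chromosome")
        if d.end > cfg.genome_length:
            raise ValueError(f"deletion {d} extends past the genome")
    for a, b in zip(dels, dels[1:]):
        if a.end > b.start:
            raise ValueError(f"overlapping deletions {a} and {b}")


def expected_k27_mean(
    cfg: SimConfig, deletions: Sequence[GenomicInterval] = ()
) -> tuple[np.ndarray, list[PreSite]]:
    """Noiseless expected reads per bin, in post-deletion coordinates.

    mean(x) = background
              + sum_j s_j * exp(-|x - x_j| / lambda) * beta**(insulators between)

    PREs falling inside a deletion contribute nothing; deleted spans are
    excised and downstream coordinates shift left.
    """
    _check_deletions(cfg, deletions)
    n_bins = cfg.genome_length // cfg.bin_size
    mids = (np.arange(n_bins) + 0.5) * cfg.bin_size
    surviving = [
        p for p in cfg.pres
        if not any(d.contains(p.position) for d in deletions)
    ]
    ins = np.sort(np.asarray(cfg.insulator_positions, dtype=float))
    ins_cum = np.searchsorted(ins, mids)  # insulators at or left of each bin
    mean = np.full(n_bins, cfg.background, dtype=float)
    for pre in surviving:
        dist = np.abs(mids - pre.position)
        n_between = np.abs(ins_cum - np.searchsorted(ins, float(pre.position)))
        mean += (
            pre.strength
            * np.exp(-dist / cfg.spread_length)
            * cfg.insulator_beta**n_between
        )
    keep = np.ones(n_bins, dtype=bool)
    for d in deletions:
        keep &= ~((mids > d.start) & (mids < d.end))
    return mean[keep], surviving


def simulate_k27_coverage(
    cfg: SimConfig, deletions: Sequence[GenomicInterval] = ()
) -> tuple[CoverageTrack, SimTruth]:
    """NB-noised coverage track around the expected spreading curve."""
    mean, surviving = expected_k27_mean(cfg, deletions)
    rng = _rng(cfg, 2, len(deletions))
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)
    track = CoverageTrack(chrom=cfg.chrom, bin_size=cfg.bin_size,
                          values=counts.astype(float))
    truth = SimTruth(
        seed=cfg.seed,
        pres=surviving,
        insulator_positions=list(cfg.insulator_positions),
        mean_curve=mean,
        extras={"deletions": [str(d) for d in deletions]},
    )
    return track, truth


# ---------------------------------------------------------------------------
# Pho-like peak heights

def simulate_pho_peak_heights(
    cfg: SimConfig,
    n: int = 1000,
    strong_frac: float = 0.10,
    weak_frac: float = 0.35,
) -> tuple[list[Peak], SimTruth]:
    """Retained split-peak heights in the observed strong/weak/null ranges.

    Exactly ceil(strong_frac * n) heights are drawn from the strong range
    (>= 400), ceil(weak_frac * n) from the weak band (100-400) and the
    rest from the retained-null band (50-100); peaks are laid out 1 kb
    apart in shuffled class order so rank classification is non-trivial.
    """
    rng = _rng(cfg, 3, n)
    n_strong = math.ceil(strong_frac * n)
    n_weak = math.ceil(weak_frac * n)
    n_null = n - n_strong - n_weak
    heights = np.concatenate(
        [
            rng.uniform(401.0, 1500.0, n_strong),
            rng.uniform(100.0, 399.0, n_weak),
            rng.uniform(50.0, 99.0, n_null),
        ]
    )
    labels = np.array(["strong"] * n_strong + ["weak"] * n_weak + ["null"] * n_null)
    perm = rng.permutation(n)
    heights, labels = heights[perm], labels[perm]
    peaks = []
    for i, h in enumerate(heights):
        start = i * 1000
        peaks.append(
            Peak(
                interval=GenomicInterval(cfg.chrom, start, start + 600),
                summit=start + 300,
                height=float(h),
            )
        )
    truth = SimTruth(seed=cfg.seed, labels=list(labels))
    return peaks, truth


# ---------------------------------------------------------------------------
# 4C counts

def simulate_4c(cfg: SimConfig) -> tuple[FourCProfile, SimTruth]:
    """Fragment counts from a power-law contact decay with planted spikes.

    Fragment means mu(d) = A * (d + d0)**(-gamma) in fragment-index
    distance d from the bait, normalized so the expected total equals
    ``fourc_depth``; planted interactions multiply their fragment's mean.
    Replicates share the truth but draw independent NB noise.
    """
    frags = [
        RestrictionFragment(
            GenomicInterval(
                cfg.chrom, i * cfg.fragment_size, (i + 1) * cfg.fragment_size
            ),
            index=i,
        )
        for i in range(cfg.n_fragments)
    ]
    bait_idx = cfg.bait_position // cfg.fragment_size
    bait = frags[bait_idx].interval
    excl = GenomicInterval(
        cfg.chrom,
        max(cfg.bait_position - cfg.exclusion_halfwidth, 0),
        min(
            cfg.bait_position + cfg.exclusion_halfwidth,
            cfg.n_fragments * cfg.fragment_size,
        ),
    )
    d = np.abs(np.arange(cfg.n_fragments) - bait_idx).astype(float)
    mu = (d + cfg.decay_d0) ** (-cfg.decay_gamma)
    mu *= cfg.fourc_depth / mu.sum()
    for pl in cfg.planted:
        if not 0 <= pl.fragment_index < cfg.n_fragments:
            raise ValueError(f"planted fragment {pl.fragment_index} out of range")
        if frags[pl.fragment_index].interval.overlaps(excl):
            raise ValueError(
                f"planted fragment {pl.fragment_index} lies inside the "
                "bait-exclusion window"
            )
        mu[pl.fragment_index] *= pl.fold
    counts = np.empty((cfg.n_fragments, cfg.n_replicates), dtype=np.int64)
    for r in range(cfg.n_replicates):
        counts[:, r] = _nb_draw(_rng(cfg, 4, r), mu, cfg.nb_dispersion)
    profile = FourCProfile(
        bait=bait, exclusion_window=excl, fragments=frags, counts=counts
    )
    truth = SimTruth(
        seed=cfg.seed,
        planted_interactions=list(cfg.planted),
        mean_curve=mu,
        extras={"bait_index": int(bait_idx)},
    )
    return profile, truth


# ---------------------------------------------------------------------------
# qPCR tables

def simulate_qpcr(
    cfg: SimConfig,
    regions: dict[str, GenomicInterval],
    n_replicates: int = 3,
    deletions: Sequence[GenomicInterval] = (),
) -> tuple[pd.DataFrame, SimTruth]:
    """Ct tables back-computed from the expected coverage curve.

    Each region's noiseless fold over background is converted to a
    percent-input value (background_percent_input * fold) and then to a
    ChIP Ct given the fixed input Ct and input fraction; Gaussian cycle
    noise (sd ``qpcr_noise_sd``) is added per replicate.  At zero noise,
    :func:`polydomain.quant.percent_input` inverts the table exactly.
    """
    mean, _ = expected_k27_mean(cfg, deletions)
    bin_mids = (np.arange(mean.size) + 0.5) * cfg.bin_size
    rng = _rng(cfg, 5, n_replicates)
    rows = []
    truth_folds: dict[str, float] = {}
    for name, iv in regions.items():
        if iv.end > cfg.genome_length:
            raise ValueError(f"region {name} outside genome")
        mask = (bin_mids >= iv.start) & (bin_mids < iv.end)
        if not mask.any():
            raise ValueError(f"region {name} covers no bins")
        fold = float(mean[mask].mean() / cfg.background)
        truth_folds[name] = fold
        pct = cfg.background_percent_input * fold
        ct_adj = cfg.ct_input - math.log2(1.0 / cfg.input_fraction)
        ct_chip_true = ct_adj - math.log2(pct)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, cfg.qpcr_noise_sd) if cfg.qpcr_noise_sd > 0 else 0.0
            rows.append(
                {
                    "region": name,
                    "replicate": rep,
                    "ct_chip": ct_chip_true + noise,
                    "ct_input": cfg.ct_input,
                    "input_fraction": cfg.input_fraction,
                }
            )
    truth = SimTruth(seed=cfg.seed, extras={"folds": truth_folds})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# one-call emitter

def _config_hash(cfg: SimConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_all(
    cfg: SimConfig,
    outdir: str | Path,
    deletions: Sequence[GenomicInterval] = (),
    qpcr_regions: dict[str, GenomicInterval] | None = None,
) -> dict:
    """Emit a full synthetic dataset (FASTA, bedGraph, truth BED, counts
    TSV, Ct CSV) plus a manifest carrying the seed and a config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, gtruth = generate_genome(cfg)
    write_fasta(genome, outdir / "genome.fa")
    track, ktruth = simulate_k27_coverage(cfg, deletions)
    write_bedgraph(track, outdir / "k27_coverage.bedgraph")
    profile, ftruth = simulate_4c(cfg)
    write_counts_tsv(profile, outdir / "fourc_counts.tsv")
    with open(outdir / "pre_truth.bed", "w") as fh:
        for pre in cfg.pres:
            fh.write(
                f"{cfg.chrom}\t{pre.position}\t{pre.position + 1}\t"
                f"{pre.klass}\t{pre.strength:g}\t.\n"
            )
    if qpcr_regions is None:
        qpcr_regions = {
            "domain_center": GenomicInterval(cfg.chrom, 110_000, 116_000),
            "background": GenomicInterval(cfg.chrom, 5_000, 11_000),
        }
    qpcr_df, qtruth = simulate_qpcr(cfg, qpcr_regions, deletions=deletions)
    qpcr_df.to_csv(outdir / "qpcr_ct.csv", index=False)
    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "files": [
            "genome.fa",
            "k27_coverage.bedgraph",
            "fourc_counts.tsv",
            "pre_truth.bed",
            "qpcr_ct.csv",
        ],
        "qpcr_truth_folds": qtruth.extras["folds"],
        "planted_interactions": [asdict(p) for p in cfg.planted],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
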