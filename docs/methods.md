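# Methods

This note documents the models, parameter choices and numerical conventions
behind `polydomain`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and rounding

Internally all intervals are 0-based half-open (BED convention). Region
strings of the form `2R:7415804..7417265` are 1-based fully inclusive on
input and output, so a printed deletion of 1462 bp round-trips exactly.
Kilobase lengths are rounded half-away-from-zero (not banker's rounding) so
that descriptions like "1.5 kb" are deterministic; `interval_length_kb`
documents this.

## Peak calling and ranking

The caller is deliberately simple: a fixed genome-wide Poisson background
rate λ (reads per bin), no local lambda and no fragment-shift model. The
upper tail P(X ≥ k) is evaluated through the regularized incomplete gamma
identity `gammainc(k, λ)`, exact for integer counts and continuous in k.
Flagged bins closer than `min_gap` bp merge into one peak; the summit is
the maximum-signal bin with ties broken leftmost, as are all ties in this
package.

Sub-peak splitting treats local maxima at or above `min_summit_height` as
candidate summits and separates two adjacent summits iff the minimum signal
between them is below `valley_fraction` (default 0.5) times the lower
summit. Candidates are resolved in descending height order, which makes the
procedure deterministic and monotone: raising `valley_fraction` can only
increase the number of sub-peaks. Sub-peak boundaries sit at the leftmost
valley minimum, so sub-peaks tile the parent exactly. The 0.5 valley
criterion is this package's choice; published valley-splitting tools do not
document a single canonical cutoff.

Classification is rank-based rather than threshold-based: after discarding
peaks below the retention floor (height 50 by default), the top
`ceil(0.10·N)` retained peaks are *strong*, the next `ceil(0.35·N)` *weak*,
the remainder *null*. Rank rules are well defined for any dataset, whereas
the familiar height cutoffs (~400 for strong, 100–400 for weak) are
dataset-specific observations; the classifier therefore reports the
empirical boundary heights so users can verify them on their own data. Note
an intrinsic wrinkle of the retention convention: peaks between the floor
of 50 and the weak boundary end up labelled *null* even though, on the
height scale, "null" is often described as "below 50". We keep the rank
semantics and expose the floor as a parameter (`retention_min_height`); a
purely height-based retention is obtained by setting the fractions
accordingly.

## 4C interaction calling

Stages, per replicate:

1. **Dispersion.** The NB dispersion α is pooled method-of-moments across
   fragments, α = Σ(v−m)/Σm² over per-fragment replicate means m and
   variances v, falling back to α = 0.1 when replicates are unavailable or
   the excess variance is non-positive.
2. **VST.** g(n) = (2/√α)·asinh(√(αn)), the analytic variance stabilizer
   for v = μ + αμ². We use the closed form rather than an external
   count-model package because the downstream robust-z statistic is
   invariant to affine rescaling — only the flattening of the mean-variance
   relation matters.
3. **Background.** Loess (local-linear, tricube weights over the
   span-fraction nearest neighbours; span 0.2 by default) of transformed
   counts on fragment midpoints. Fragments overlapping the bait-exclusion
   window — by default 6 kb centered on the bait — are excluded from the
   fit but still receive predictions. Local-linear fitting is exact on
   globally linear data, which anchors the numerical tests.
4. **P-values.** Residuals are standardized by s = 1.4826·MAD and referred
   to a one-sided standard normal (enrichment only). The one-sided normal
   null on robust-z loess residuals is this package's documented choice;
   viewpoint-based 4C analyses of this style typically leave the exact
   construction open.
5. **FDR.** Benjamini–Hochberg step-up per replicate, across all fragments
   of the bait chromosome only.
6. **Consensus.** Significant iff p < 0.01 in every replicate and q < 0.1
   in at least one; excluded-window fragments are never called. The loess
   fit is per replicate (not pooled), which the per-replicate p-value
   requirement makes natural.

The in-silico digest cuts at every occurrence of an unambiguous recognition
site, with a configurable cut offset inside the site (default at the site
start; `cut_offset=1` reproduces EcoRI's G^AATTC). Overlapping site
occurrences all cut; zero-length fragments are suppressed.

## Motif census

Scanning is plain IUPAC consensus matching (regex with lookahead so
overlapping matches are all counted; no collapsing rule). `N` in the
*sequence* matches nothing, including pattern `N`. Minus-strand hits are
matches of the reverse-complement pattern reported in plus-strand
coordinates; palindromic patterns are not double-counted. The scan window
is 500 bp either side of the peak summit (1 kb total), clipped at
chromosome ends.

The shipped motif strings (Pho `GCCAT`, GAGA `GAGAG`, GTGT `GTGT`, Zeste
`YGAGYG`, Spps `GGGCGG`, Dsp1 `GAAAA`, Grh `WCCGGTT`) are editable
literature-informed consensus choices, each tagged with a source note; they
are defaults, not assertions about any particular published census, and
every census output records the strings used. Short patterns (4–5 bp) have
substantial chance hit rates in 1 kb windows — GTGT expects ~8 chance hits —
so absolute counts should be read against that background.

## Quantification

Broad domains merge bins ≥ `enrich_threshold` × background (default 3×)
separated by ≤ `max_gap` bp (default 2 kb). The defaults were chosen so
that, under the generator's default NB noise (background 5 reads/bin,
dispersion 0.1), pure background yields no multi-bin domains while the
simulated domain is recovered as one block; both are exposed as parameters.

Percent-input applies the dilution correction before the ΔCt: with input
fraction f, adjusted input Ct′ = Ct_input − log₂(1/f) and recovery
= 2^(Ct′ − Ct_ChIP). Condition comparisons default to Welch's unequal-
variance t-test (the safer reading of a generic "Student's t-test";
`equal_var=True` restores the pooled form), two-sided, unpaired, flagged at
p ≤ 0.05.

## The generator

The generator formalizes a cooperative-PRE cartoon as a sampling model, not
a biophysical claim:

- **H3K27me3**: mean(x) = bg + Σⱼ sⱼ·exp(−|x−xⱼ|/λ)·β^(#insulators between
  x and xⱼ), NB noise. Defaults: 200 kb genome, 100 bp bins, bg = 5
  reads/bin, λ = 5 kb, dispersion 0.1; four strong PREs (strengths
  430–620) and ten weak ones (140–300) spanning ~48–150 kb, so the marked
  region is of order 100 kb. Two weak PREs carry no GAGA motifs in the
  generated genome, mirroring the observation that some weak sites are
  non-canonical.
- **Deletions** are applied to the mean before noise: deleted PREs
  contribute nothing and deleted spans are excised, so mutant coordinates
  are post-deletion and WT/mutant datasets share one truth machinery.
- **4C**: fragment means A·(d+d₀)^(−γ) in fragment-index distance from the
  bait (γ = 1, d₀ = 1 fragment), normalized to 10⁵ expected reads per
  replicate over 500 × 400 bp fragments, planted interactions as
  multiplicative folds, independent NB noise per replicate.
- **qPCR**: Ct values back-computed from the expected coverage curve with
  Gaussian cycle noise (sd 0.15 cycles), so at zero noise the percent-input
  arithmetic inverts the table exactly.
- **Peak heights** for classification tests are drawn directly in the
  observed class ranges (strong > 400, weak 100–400, retained-null 50–100)
  in exact 10/35/55 proportions.

Determinism: every sampler derives its generator from
`SeedSequence([seed, stage_tag, ...])`, so outputs are pure functions of
the config and replicates get independent but reproducible streams.

**What passing tests show — and don't.** Recovery and FDR results on this
generator demonstrate internal consistency of the pipeline under its own
idealized assumptions (stationary background, exponential/power-law decay,
independent NB noise, no mappability or restriction-site density
artifacts, no trans contacts, no copy-number or fixation-efficiency
effects). They do not certify performance on real ChIP-seq or 4C-seq
libraries, where background structure and fragment-level biases are richer.

## Known limitations

- The peak caller is a fixed-λ scan: no input-track correction, no local
  background, no fragment-length model.
- Interaction calling is cis-only on the bait chromosome; trans contacts
  are out of scope.
- The motif module does consensus matching only — no position-weight
  matrices, no conservation filtering.
- Barcode demultiplexing is exact-match with no mismatch tolerance.
- Problem sizes in the test suite (500-fragment 4C maps, 200-null-run FDR
  checks, 1 kb scan windows) are chosen to make the statistical checks
  sharp yet quick; they are smaller than genome-scale datasets by design.
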