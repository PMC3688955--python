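# Methods

## Signal model and calibration

A Sanger electropherogram registers, for each basecall, four dye-channel
intensities.  The height of the called peak is repeatable for a given
sequence context: it depends on the identity of the base and the bases
preceding it, and across replicate runs of the same sequence varies by about
5% per position once runs are brought to a common scale.  tracemix exploits
this by calibrating an *intrinsic profile* — the expected intensity E(i) and
its standard deviation at every reference position — from a set of clone
reads of the same or a highly similar amplicon.

Normalization puts every run on a 1000-unit scale.  Clone reads are scaled
so that the mean called-channel call-point intensity over the chosen region
is 1000.  Direct (mixed-amplicon) reads are scaled on per-position sums of
the four channels' window maxima instead: in a mixture every channel can
carry real signal, and minor-variant peaks do not always crest exactly at
the call point, so each channel's maximum over a 5-scan window centred on
the call point (window width configurable) is the honest per-channel
estimate.  Window extraction truncates at read ends; `N` calls are kept but
excluded from scaling statistics.

Clone reads are aligned to the reference with gaps permitted only inside
declared homopolymer tracks, placed canonically at the 3′ end of each track.
Per position, the expected value is the mean of the clones carrying the
majority base (population SD, n in the denominator — a descriptive statistic
over the full clone set); minority-allele means at substitution columns are
retained separately for substitution quantification.  Positions covered by
fewer than 3 clones (configurable) are treated as uncalibrated and excluded
from fitting windows.  Forward- and reverse-primer clones build separate
profiles, each in its own read frame (coordinates counted from the primer);
a direct read is always fitted against the profile of its own direction,
which makes the frame-shift arithmetic identical for both primers.

## The proportion model

A length variant with signed shift s (deletion < 0) reads identically to the
reference up to its indel track and then shows, at read position u, the
reference position u − s.  The expected signal of a hypothesized mixture is
the proportion-weighted superposition of the shifted profiles, routed to the
base found at each shifted position — linear in the proportions.  The fit
minimizes the sum of squared differences between observed and simulated
intensities per (position, base) over a window of at least 200 positions
following the indel site (a sums-only objective is available as an option).
Windows with fewer than 50 usable positions are refused.

Two numerical choices matter:

- **Guard band.** Within the variable track and for a few positions after
  it (default 3, the synthetic context order), the preceding sequence
  context genuinely differs between variants, so the shifted-profile
  superposition is not a valid expectation there; these positions are
  excluded from the objective.  Positions whose shifted index leaves the
  calibrated profile are likewise dropped, never extrapolated.
- **Scale profiling.** Observed and simulated signals are each normalized
  run-wise, which leaves a residual global scale mismatch of a percent or
  two over any particular window.  The objective therefore profiles out a
  free scalar on the observed window analytically (the residual becomes
  ‖Mp‖² − (o·Mp)²/‖o‖²); without this the fit would trade scale error
  against proportion error.

The search is an exhaustive simplex grid at 1% resolution (coarse 5% grid
followed by a ±5-point local 1% refinement when more than 3 variants are
fitted, keeping the search exact for grid-aligned optima), with ties broken
toward fewer nonzero variants and then lexicographically.  A constrained
quadratic polish (SLSQP on the simplex) then interpolates the optimum
between grid points; length percentages are reported to 2 decimals.
Noiseless self-consistency is exact: fitting a simulated mixture returns the
generating proportions bit-for-bit on the grid.

For a region with two single-nt deletion sites the per-molecule deletion
count is the sum of two indicators, so the expectation identity
d_near + d_far = 2·P(L−2) + P(L−1) holds exactly.  The site nearest the
primer is fitted directly over the inter-site window; the total-length
distribution is fitted downstream of the far site (where the frame offset is
the total shift); the far site's percentage follows from the identity,
clamped to [0, 100].  Input length distributions must sum to 100 ± 2
(rounding slack).

## Substitution quantification

At a clean position, fraction(X) = (I_X/E_X) / (I_X/E_X + I_Y/E_Y), where
E comes from clones carrying each base when available and otherwise falls
back to the consensus expectation (channel equivalence assumed for rare
alleles).  With E_X = E_Y this reduces to the raw peak-height ratio.  Inside
a frame-shifted region the fitted mixture supplies the per-channel expected
background; the candidate is the base with the largest positive excess, and
its molecule fraction is the excess divided by the expected intensity of
that base at the dominant frame's reference coordinate.  Substitution
percentages are always integer-rounded (half away from zero): a single
position carries the information, unlike the hundreds of positions behind a
length fit.  Calls below a noise floor are no-calls rather than zeros.

## Thresholds, QC and profiles

Noise QC measures, over a caller-designated clean (invariant) region, the
mean of the largest non-called channel's window intensity relative to the
mean called intensity; reads above 10% are excluded from quantitative
analysis.  The maximum (rather than the mean) of the three off channels is
the conservative default and is configurable.  Detection thresholds are 5%
for length variants (set to 0 below it) and 10% for substitutions (dropped);
surviving percentages are *not* renormalized, so region totals may fall
slightly short of 100 — matching how such estimates are honestly reported.
Profile comparison counts features whose thresholded values differ; both the
strict any-difference criterion (default) and a permitted-error margin
criterion (5 points for length-type features, 10 for substitutions) are
implemented, the latter being the appropriate lens for same-strain pairs
whose values differ only by replicate-level scatter.

## Synthetic data

The generator emulates the statistical structure the method relies on, not
the chemistry.  Intrinsic intensity is a deterministic function of the base
and its preceding k-mer (k = 3): the base sets the overall level (±25%) and
each preceding base modulates it multiplicatively with influence halving per
position of distance (18%, 9%, 4.5%) — so nearby context matters most, and
frames that share local sequence share expected intensities.  Per-peak
multiplicative scatter is lognormal with SD 0.05 by default (the observed
run-to-run repeatability), off-channel baseline noise is 2% of the position
total by default (QC-fail fixtures use 12%, straddling the 10% bar), and
minor peaks are attenuated at the call point by up to 20% relative to their
window maximum, reproducing why direct reads are summarized by window
maxima.  Clone reads draw one template; direct reads superpose the variant
templates at their true proportions position-by-position, exactly as
co-migrating templates superpose in a real trace, with substitution truths
splitting the affected molecules' signal between the two bases.  Default
structure mirrors the study amplicon: ITS1 of 254 nt with a TTT track at
positions 177–179, ITS2 of 323 nt with tracks at 10–13 and 246–247, 5.8S of
157 nt, and the four conserved border motifs placed verbatim; 48 clones per
calibration set.  Everything is bit-reproducible under a fixed seed, and
every dataset is written with a JSON truth manifest.

What the generator does not emulate: peak-shape rendering at scan
resolution beyond what window extraction needs, dye blobs, mobility shifts,
quality scores, basecalling errors, or PCR-level distortions (template
titration effects, polymerase slippage).  Passing tests therefore
demonstrate the estimator's correctness under the method's own signal
model, not robustness to every artefact of real electropherograms.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| run mean | 1000 units | common intensity scale after normalization |
| clones | 48 | calibration set size per direction |
| window | ≥ 200 positions | comparison window after an indel site |
| grid | 1% (coarse 5%) | proportion search resolution |
| noise SD | 0.05 | per-peak multiplicative scatter |
| noise QC bar | 10% | off-channel fraction above which a read is excluded |
| length threshold | 5% | below it, a length variant is reported 0 |
| substitution threshold | 10% | below it, a substitution is not considered |
| guard band | 3 positions | post-track positions excluded from the objective |
| min calibrated clones | 3 | positions below this are not fitted |

Monte-Carlo checks in the tests and the acceptance script use 100 seeded
trials per recovery rate and 20–40 seeds for error-scaling properties; these
sizes keep each check well-resolved (binomial SE < 3 points at rate 95%)
while the whole suite runs in well under a minute.

## Known limitations

- Substitutions within the guard band of an indel site sit in a context
  that differs between frames; their quantification inherits a bias of the
  order of the context difference, which is why single-position results
  carry a 10-point permitted error.
- Positions a few nt downstream of a polymorphic column mix two contexts in
  the clone average, inflating the profile SD there (such positions are
  flagged by `profile_qc`).
- At most two indel sites per region are supported; joint fitting of
  substitutions and lengths in one objective is out of scope.
- The exact objective used in the original quantifications is not public;
  least squares (with the scale profiling described above) is this
  package's choice and is flagged as such.
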