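# Methods

## Optical algebra

A refraction is a sphero-cylinder (S, C, θ) referenced to a vertex plane
*d* mm in front of the cornea. Input files use negative-cylinder
notation; transposition to the positive form is S' = S + C, C' = −C,
θ' = θ ± 90 (kept in (0, 180]). An entered axis of 0 — the conventional
way of writing a plano target ("0, 0, 0") — is stored as 180, avoiding
the duplicate meridian label. Vertex propagation treats the two
principal meridians independently with the effectivity relation
F' = F / (1 − d·F), d being the signed plane shift in metres; the
relation has a pole at F = 1/d (≈ +83 D for a 12 mm shift), which is
reported as a domain error naming the offending meridian. Dioptre
values are never rounded internally; rounding to 0.01 D happens only
when figures are annotated.

SEQ = S + C/2 is invariant under transposition; DEQ = |SEQ| + |C|/2
satisfies DEQ ≥ |SEQ| with equality iff C = 0. SEQ accuracy, DEQ and
stability analyses use the refraction at the plane the user entered;
only the astigmatism vector analyses force conversion to the corneal
plane (0 mm). This split is configurable (`seq_plane='corneal'`); the
default reflects the convention that manifest SEQ outcomes are reported
at the measurement plane while vector planning is corneal.

## Visual acuity

Acuity tokens are 20/XX Snellen denominators with an optional signed
letter suffix. logMAR = log₁₀(XX/20) − letters·ε with ε = 0.02 logMAR
per letter by default (five-letter lines); ε is configurable because
charts differ. Decimal acuity is 10^(−logMAR). Snapping a logMAR value
back onto the chart searches all configured lines with offsets −4..+4
and prefers the smaller |offset| on ties, making the conversion the
exact inverse on representable values. Line changes are
(logMAR_pre − logMAR_post)/0.1 rounded half-away-from-zero, so gains and
losses bin symmetrically.

The efficacy and safety indices are ratios of group means of decimal
acuity (the mean-of-per-eye-ratios variant is available behind
`AcuityConfig.per_eye_ratios`). The baseline is the preoperative CDVA,
except for cataract surgery where panels A/B and the efficacy index
compare against the postoperative CDVA — pseudophakic eyes have no
meaningful preoperative best-corrected reference. Refractive lens
exchange and phakic IOL procedures keep the preoperative baseline.

## Astigmatism vectors

All vector work happens in doubled-angle space, where a cylinder C @ θ
is (C cos 2θ, C sin 2θ): clinically identical meridians (θ, θ+180°) map
to the same point and orthogonal cylinders are antipodal, so astigmatic
changes compose additively. TIA (target − preop) and SIA
(postop − preop) are plain vector differences of corneal-plane,
positive-cylinder refractions. CI = |SIA|/|TIA| (>1 overcorrection);
the angle of error is half the signed doubled-angle from TIA to SIA,
in (−90°, 90°], positive counterclockwise. Eyes with |TIA| = 0 have no
defined CI or AoE and are excluded from those panels; their count is
reported in the panel annotation rather than silently dropped. The
magnitude of error and difference vector are computed implicitly by the
same arithmetic but not plotted; polar TIA/SIA/DV distribution plots
are out of scope.

## Panels

Panel content is computed into plain data (`PanelData`) before any
drawing, and identical inputs produce identical panel content
bit-for-bit. Within-threshold summaries use inclusive boundaries
("within 0.50 D" means |x| ≤ 0.50); the stability change criterion is
strict (|ΔSEQ| > 0.50 D does count, exactly 0.50 does not). Cumulative
acuity curves count an eye at a line when its logMAR is at or below the
line threshold plus 1e-9 (absorbing float representation of letter
offsets). Line-difference histograms use the exhaustive partition
{≤−2, −1, 0, +1, ≥+2}; CI and AoE histograms use equal-width bins
(defaults 0.1 and 5°, AoE bins centred on zero) covering the data
range, so every percentage partition sums to 100 over included eyes.
Panel F is the SEQ stability series (preop plus up to five
postoperative time points, per-time-point Ns, and the percentage of
eyes changed between a selected pair of points) whenever at least two
postoperative time points are populated in every group; otherwise the
DEQ accuracy histogram takes its place. Scatter panels (E, H) draw the
identity and fitted lines with axes padded 10 % beyond the data range.

Two-group runs attach one automatic comparison per panel. Reporting
conventions leave the exact test variable per panel open; this package
uses: A/B postop UDVA (logMAR), C CDVA line
change, D SEQ error, F selected-pair SEQ change (or DEQ), G postop
astigmatism magnitude, I CI, J AoE; E and H are regression panels and
carry no hypothesis test. Paired designs compare row-aligned eyes and
drop pairs in which either member's quantity is undefined.

## Statistics

Normality is screened with the Kolmogorov–Smirnov test using the
Lilliefors correction, since the null parameters are estimated from the
sample — the uncorrected KS is markedly anticonservative there.
Samples with n < 4 or zero variance are non-assessable and treated as
non-normal. The parametric branch (unpaired/paired t) requires both
samples to pass at α = 0.05; otherwise Mann–Whitney U or Wilcoxon
signed-rank is used. All tests are two-sided. Cohen's d is reported on
every comparison regardless of branch — unpaired: mean difference over
the pooled (n−1)-weighted SD; paired: mean difference over the SD of
differences — with degenerate (zero-spread) cases flagged as
not-computable rather than infinite. Identical paired samples
short-circuit to p = 1, d = 0. Regressions are ordinary least squares
with R² the squared Pearson correlation. No multiplicity correction is
applied across panels, and three-or-more-group designs are out of
scope.

## Rendering

One TIFF per panel at 400 dpi (4×3 in) and a 2-column × 5-row composite
page at 1200 dpi (5×8 in), resolution embedded in the TIFF metadata;
colours and group names are configurable. The composite page size is
chosen so the 1200 dpi raster stays within ordinary memory; styling is
intentionally plain.

## Synthetic cohorts

The generator samples preop sphere ~ Normal, cylinder magnitude
~ |Normal|, axis uniform (or with-the-rule biased), quantized to
clinical resolution (0.01 D, 0.1°). Treatment is applied in the
analysis's own coordinates: TIA is scaled by a CI drawn from
Normal(ci_mean, ci_sd) (truncated at 0) and rotated by a Normal axis
error; achieved SEQ is the target SEQ plus a bias and Normal noise.
Uncorrected postop acuity follows logMAR = max(baseline,
k·DEQ) + noise with k = 0.3 logMAR/D — a deliberately simple monotone
defocus-acuity link — snapped to chart tokens; corrected acuity moves
by a sampled whole-line change. Stability series add a per-time-point
drift and can shift a fixed leading fraction of eyes by a fixed
magnitude between two time points, making the changed-eye fraction
exact by construction.

Because CI and axis error act directly on the doubled-angle vectors,
parameter recovery through the full pipeline is exact up to sampling
and quantization noise; this is what the recovery tests exercise
(n = 500: CI mean within 0.02, SEQ bias within 0.03 D, shifted fraction
exact). The generator emulates distributional shape, not clinical
realism: it has no enhancement/retreatment structure, no correlation
between fellow eyes beyond shared preop refractions in paired designs,
no complications, and acuity noise is homoscedastic. Passing tests
therefore validate the analysis machinery, not any clinical claim.

## Problem sizes and determinism

Default test and acceptance runs use cohorts of 25–500 eyes and 100–2000
simulation replicates — large enough that the binomial/standard-error
bands asserted in the tests have comfortable margins, small enough for
interactive runs. Every stochastic path takes an explicit seed;
`scripts/acceptance.py` derives all randomness from its `--seed`.

## Known limitations

- Acuity input is Snellen-denominator only; logMAR data enter via the
  bundled conversion table, and metric-chart notation is unsupported.
- Corneal/keratometric astigmatism, IOL power calculation and
  flattening/torque decompositions are out of scope.
- The Lilliefors table-based p-values are mildly conservative at large
  n (measured null rejection ≈ 4 % at n = 500), which nudges the
  dispatcher toward parametric tests; the overall two-group type-I
  error stays within the 5 % ± 1.5 % band asserted in the tests.
- XLSX output pins document timestamps for reproducibility, but zip
  container metadata may still differ across library versions; the CSV
  dialect is byte-stable.
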