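# Methods

## Measurement model

A lateral-flow immunoassay (LFIA) strip for a small-molecule analyte
(melamine in urine, reported in ppb = ng/mL) is read by a reflectance
microspectrometer. Three regions are scanned: the control line (C), the
test line (T), and a white reference area (W). Line color comes from
colloidal-gold antibody conjugates, whose surface-plasmon extinction peaks
in the 520–550 nm band. The per-line absorbance is

    A(λ) = −log10( S_line(λ) / S_W(λ) )

Dead or saturated pixels (non-positive intensity ratio) are flagged invalid
pointwise and excluded from peak search rather than voiding the scan.

The absorbance profile is smoothed with a Savitzky–Golay (SG) filter and
summarized as a baseline-corrected band peak:

    ΔA = max{ A(λ) : 500 nm ≤ λ ≤ 600 nm } − A(650 nm)

The 650 nm deduction removes the instrument baseline; it may leave ΔA
negative on blank strips, and no clipping is applied at this stage. The
pipeline order is fixed — absorbance, then smoothing, then peak search —
because SG is linear in absorbance but not in raw counts, and swapping the
order changes the result.

The per-strip statistic is the normalized line contrast

    Diff = 1 − ΔA_T / ΔA_C

The assay is competitive: more analyte means a fainter test line, so Diff
increases with concentration, from ≈ 0 (blank) toward 1 (saturating).
ΔA_C ≤ 0 means the control line failed and the strip is void. Diff > 1
(negative ΔA_T from blank noise) is retained, because clamping would bias
the blank SD — and hence the detection limit — downward.

## Calibration

The standard curve is a one-phase association in x = log10(concentration):

    Y(x) = y0 + (plateau − y0) · (1 − e^(−k·x))

fitted by bounded nonlinear least squares (trust-region reflective) to the
nonzero standards only; the blank is excluded because log10(0) is
undefined. Y(0) = y0 corresponds to 1 ppb, not 0 ppb. Initialization is
deterministic — y0 from the minimum observed Diff, plateau from the
maximum, k = 1/(x-range) — with a fixed ladder of k rescalings
(×1, ×0.1, ×10, ×0.01, ×100) as restarts; the lowest-cost converged
solution satisfying plateau > y0, k > 0 wins, so refits are reproducible
without random seeds. R² = 1 − SS_res/SS_tot over the fitted points. A flat
response (zero Diff variance) is reported as a fit failure rather than a
degenerate curve.

Inversion is closed-form on (y0, plateau):

    x = −(1/k) · ln(1 − (Diff − y0)/(plateau − y0)),   c = 10^x

with censoring flags: Diff < y0 → 0 ppb (`below_lod`); Diff ≥ plateau →
calibration upper bound (`above_range`); non-finite → `unresolvable`;
Diff = y0 maps to exactly 1 ppb in range. When the model carries a
detection limit, in-range results beneath it are flagged `below_lod`.

## Detection limits

From blank replicate concentrations (blank strips run through the full
pipeline; Diff at or below the curve floor maps to 0 ppb):

    LOB = mean_blank + 1.645 · SD_blank      (95% one-sided limit)
    LOD = mean_blank + 3 · SD_blank

SDs use the n−1 denominator throughout. Limits are computed on the
concentration scale because that is the scale they are reported on.

## Validation statistics

* **Reproducibility** — mean, SD, CV% per condition; classes:
  excellent (CV < 10%, strict), good (10–20%), poor (≥ 20%). CV exactly
  10% is "good".
* **Interference** — two-sided paired t-test of concentrations with vs
  without each substance, α = 0.05. Identical pairs return t = 0, p = 1 by
  convention so the "all p > 0.05" decision rule is always defined.
* **Method agreement** — ICC(A,1) (two-way random, absolute agreement,
  single measures — the form that, like Bland–Altman, penalizes constant
  bias; other forms selectable), Pearson r, and Bland–Altman bias ±
  1.96·SD limits on differences platform − reference. ICC classes at
  0.5 / 0.75 / 0.9.

## Synthetic spectra

The simulator emulates the forward measurement chain on the instrument's
300–1000 nm grid at 0.55 nm pitch: a broad Gaussian LED illuminant with a
2% floor (strictly positive), Gaussian plasmon absorbance bands
(center 535 nm, σ 40 nm) of amplitude 0.8 AU (C-line) plus a 0.02 AU
baseline offset, and independent multiplicative Gaussian noise of
fractional SD 0.25% per spectrum — the instrument's stated overall noise
level. The test-line amplitude is amplitude_C · (1 − Diff_truth(c)) with
Diff_truth from a truth calibration model (defaults y0 = 0.05,
plateau = 0.95, k = 1.2), so the generative and fitted families coincide
and parameter recovery is well posed. The blank responds at the curve
floor max(0, y0).

Because all pipeline operations are linear in absorbance and the C/T
profiles are proportional, the noiseless simulator→pipeline round trip
recovers Diff_truth to machine precision; this is the package's strongest
self-consistency check.

What the simulator does **not** emulate: strip-to-strip chemistry
variability (antibody loading, membrane flow), wavelength-dependent or
shot noise, drift, and real urine-matrix effects. Simulated precision
(CV ≈ 0.8% at 10 ppb) is therefore better than a physical assay's
(reported intraday CV 6.53%), and simulated blank statistics are censoring
artifacts, not instrument truth. Passing tests demonstrate correctness of
the computations, not field performance.

## Numerical choices and problem sizes

* SG defaults: window 11 points, order 3 (≈ 6 nm at native pitch,
  consistent with the ~5 nm optical resolution); endpoints handled by
  fitting the local polynomial over the one-sided terminal window, never
  by padding.
* Peak search uses discrete grid maxima, ties to the lowest wavelength;
  at ~5 nm effective resolution sub-sample refinement is unwarranted.
* The 650 nm baseline is linearly interpolated between bracketing grid
  samples, since grids need not contain 650.0 exactly.
* Wavelength grids must match exactly across C/T/W of one scan;
  resampling is deliberately unsupported so acquisition faults surface.
* Simulation sizes mirror the study design: 8 standards × 5 replicates
  per panel, 20 intraday replicates, 24 method-comparison samples; the
  type-I-error Monte-Carlo uses 10⁴ paired tests of 8 pairs.

## Known limitations

* The calibration family is fixed to one-phase association; 4PL/5PL
  alternatives are out of scope.
* No stray-light/dark-current correction (done inside the instrument) and
  no decoding of raw sensor images.
* Published human-sample agreement numbers cannot be reproduced from
  public data; agreement code is validated against independent ANOVA
  oracles and synthetic coverage instead.
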