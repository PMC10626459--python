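# Methods

## Optical model

The eye is reduced to two coaxial thin lenses in the paraxial regime: a
cornea of power `Fc` (the biometer's "Average K", taken at face value with
no keratometric-index reconversion) and an IOL a distance `d` behind it,
with aqueous humour (n = 1.336) between them and silicone oil (n = 1.403)
filling the vitreous cavity. Reduced vergence `V = n/l` propagates as
`V' = n V / (n - d V)` across a translation `d` and adds thin-lens powers
at each surface. Requiring parallel light to focus on the retina, at
`AL - ELP` behind the IOL plane inside the oil, yields the closed form

    F_IOL = n_oil / (AL - ELP) - n_ah * Fc / (n_ah - ELP * Fc).

The same expression with `n_ah` in place of `n_oil` is the water-filled
counterpart used by conventional formulas; their difference is exactly
`(n_oil - n_ah) / (AL - ELP)`, which spans 3.0–5.0 D as the retina-to-IOL
distance runs from 22.3 down to 13.4 mm — the quantitative content of the
surgical rule of thumb of adding 3–5 D for an oil-filled eye.

Assumptions worth keeping in mind: thin cornea (single refracting
surface), full oil fill with a flat interface at the IOL, spherical
correction only (no toricity), and a single scalar `d` standing for the
IOL's optical plane. The refractive indices default to 1 / 1.336 / 1.403
and are configurable (`OpticalMedia`) because silicone oils of other
viscosities have slightly different indices.

### Independent oracle

`vergence_trace_oracle` performs the stepwise propagation numerically
(cornea, translation, IOL, image distance in oil) without ever using the
closed-form power expression. The closed form is validated by root-solving
the traced image distance onto the retina: over 1000 random geometries in
the physiological box (AL 20–30 mm, K 38–48 D, ELP 3–7 mm) the two routes
agree to better than 1e-9 D (observed ~4e-14 D).

### Inverting for the implied ELP

`implied_elp` solves `F_IOL(elp) = F` for `elp`. The residual is **not**
monotone: both `n_oil/(AL - e)` and the equivalent corneal power grow
toward their respective poles, and the derivative vanishes at the
closed-form stationary point

    e* = (sqrt(n_oil) n_ah - sqrt(n_ah) Fc AL) / (Fc (sqrt(n_oil) - sqrt(n_ah))).

The bracket (0.1 mm, min(AL, n_ah/Fc) − 0.1 mm) is split at `e*` when it
lies inside and each monotone piece is Brent-solved to a residual below
1e-9 D. Where the root is unique the round trip
`implied_elp(so_iol_power(g))` recovers the ELP to ~2.5e-14 m. On a thin
ridge of very long, steep-cornea geometries the power is locally flat in
ELP and genuinely 2-to-1; when both roots are anatomically plausible
(inside 2–9 mm) no inverse exists and the solver raises a documented
"ambiguous" error rather than guessing (≈0.2–0.3% of uniform draws from
the box). When only one root is plausible, that one is returned.

## ELP model and axial-length preconditioning

`ELP = a0 + a1·AC + a2·AL` (Haigis), in millimetres, converted to metres
only at the vergence boundary (`pipeline.compute_eye`). Per-lens optimized
triples can be loaded from a YAML registry; when only a manufacturer
A-constant is known the standard conversion `a1 = 0.4, a2 = 0.1,
a0 = (0.62467·A − 68.747) − 0.4·3.37 − 0.1·23.39` is used and the entry is
marked "A-constant conversion". The recentring constants 3.37 mm / 23.39 mm
are the population means of the classical personalized-ACD tradition — a
community convention, not a fitted value. The six lens models listed in
the packaged registry carry nominal A-constants only; an optimized triple,
when available, always takes precedence.

Axial lengths above 26 mm (strictly) are first mapped through the
Wang-Koch first-generation linear adjustment for the Haigis formula,
`AL' = 0.9621·AL + 0.6763`, shipped as overridable configuration
(`WangKochCoefficients`) because the coefficients belong to the external
adjustment literature, not to this package. The jump at the threshold is
0.31 mm. The adjusted AL feeds **both** the ELP model and the vergence
formula; using two different axial lengths would be incoherent.

Constructor-level guards keep everything physiological: `a1, a2 ∈ [0, 1]`
and the constants must place the ELP inside (2, 9) mm over the AL 20–30 mm
× AC 2–4 mm box (checked at the box corners — the model is affine).

## Validation statistics

The clinically required power is `implanted + postoperative spectacle
sphere`, plain signed addition with no vertex-distance correction: that is
how the cohorts were analysed, and it reproduces their published summaries
exactly. Prediction error is theoretical − clinical; summaries use the
sample (n−1) SD throughout. Absolute-error bands are half-open on the
left: [0, 0.5), [0.5, 1), [1, 1.5), [1.5, 2), [2, ∞) — with the packaged
data the observed errors 1.56 and 1.69 fall in the fourth band, matching
the published counts (4, 0, 5, 2, 2).

The agreement statistic is ICC(3,1): two-way mixed-effects, consistency,
single measures, from the n×2 ANOVA mean squares,
`(MSR − MSE)/(MSR + MSE)` for k = 2, with the classical F-based confidence
interval (`F0 = MSR/MSE`; bounds `(F − 1)/(F + k − 1)` at
`F0 / F_{1−α/2}(n−1, (n−1)(k−1))` and `F0 · F_{1−α/2}((n−1)(k−1), n−1)`).
Consistency (rather than absolute agreement) is the right variant here
because a constant offset between formula and clinic should not count as
disagreement; it is also the variant that reproduces the published 0.771
(95% CI 0.405–0.924) from the oil-dependent table. The implementation is
hand-written from sums of squares and is cross-checked in the test suite
against both a brute-force loop ANOVA (500 random datasets, ≤1e-10) and
pingouin's ICC(C,1). The paired t-test and the advisory Shapiro–Wilk check
delegate to scipy.

## Packaged cohorts and their known inconsistencies

The two fixture tables are transcribed cell-for-cell (including one
four-decimal power, 18.998). Two rows of caution, flagged by the code
rather than smoothed away:

* **Oil-dependent row A08** (AL 20.37 mm, K 46.31 D, recorded theoretical
  power 26.43 D): inverting the formula puts the implied ELP at 1.92 mm,
  far out of the plausible 3–8 mm range the other 12 rows occupy
  (4.2–4.8 mm). Any Haigis-like ELP (~4.6 mm) would predict ≈34 D for this
  eye, so the recorded power is inconsistent with the stated model; the
  row is kept as printed.
* **First-stage cohort (group B) summary**: the published clinical summary
  (22.84 ± 3.42 D) and ICC (0.811, CI 0.573–0.923) do not reproduce from
  the table under the same conventions that reproduce every oil-dependent
  number exactly; plain addition gives 22.79 ± 3.36 and ICC 0.629. A
  transcription inconsistency in the table is the likely cause. The
  pipeline emits these values with a "known-discrepancy" annotation. The
  group-B theoretical summary (23.10 ± 3.08 D) does reproduce.

Because the per-lens optimized Haigis triples behind the recorded
theoretical powers were never published, those powers are **inputs** to
the validation pipeline, not recomputed; the formula path itself is
verified by the vergence oracle, the inversion round trip and the
plausibility sweep instead.

## Synthetic cohort generator

`generate_synthetic` draws biometry from truncated normals matched to the
oil-dependent cohort: AL ~ N(22.8, 1.3²) mm on (20, 30), K ~ N(43.9, 1.8²) D
on (38, 48), ACD ~ N(2.94, 0.31²) mm on (2, 4.5), independently per eye.
Outcomes are synthesized from the model itself: the implanted power is the
formula's prediction rounded to the 0.5 D steps lenses come in, and the
postoperative sphere absorbs the remainder plus N(0, 0.6²) D noise — 0.6 D
being a typical short-term refraction repeatability. What this emulates is
a cohort whose outcomes scatter around the formula's own predictions; what
it deliberately does not emulate is correlation between AL, K and ACD,
flat-cornea model failure, measurement bias through oil, or surgical ELP
variability. Passing pipeline tests on synthetic data therefore
demonstrate statistical plumbing, not clinical accuracy.

## Numerical choices and problem sizes

* Millimetres at every public boundary, metres inside the vergence core;
  the conversion happens once, in `pipeline.compute_eye`.
* Brent root-finding with xtol 1e-13 for both the ELP inversion (residual
  tolerance 1e-9 D) and the oracle cross-check.
* Degenerate statistics (zero between-subject variance, zero-variance
  paired differences) warn and flag rather than raise, so batch runs
  survive pathological subgroups.
* Test and acceptance sweeps use 500–1000 random geometries or datasets;
  at these sizes every property check completes in seconds and the
  observed deviations sit 4–5 orders of magnitude below the asserted
  tolerances, so larger sweeps would add nothing.

## Limitations

Thin-lens cornea and scalar ELP (no thick-lens or ray-height model);
full-fill oil only (no partial fill or meniscus); spherical equivalent
only; the A-constant conversion is a fallback, not a substitute for
optimized constants; and the clinical evidence packaged here is small
(13 + 19 eyes, one centre) — the statistics reproduce that evidence, they
do not extend it.
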