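# soiol — IOL power calculation for silicone-oil-filled eyes

Some eyes keep their silicone-oil tamponade permanently: after
vitreoretinal surgery for retinal detachment, proliferative diabetic
retinopathy or similar disease, removing the oil would re-detach the
retina, so the eye stays oil-filled ("silicone-oil-dependent"). When such
an eye later needs cataract surgery, every standard intraocular lens (IOL)
power formula — SRK/T, Haigis, Barrett Universal II — assumes the vitreous
cavity is filled with vitreous or water (refractive index 1.336). Silicone
oil has index 1.403, so those formulas under-power the lens by several
diopters and surgeons have resorted to adding "3–5 D" by rule of thumb.

`soiol` implements a closed-form vergence solution for this situation,
plus the retrospective validation-statistics pipeline used to test it
against clinical outcomes. It is a Python library first (with a small
`soiol` command-line wrapper) aimed at ophthalmic-optics researchers and
anyone auditing IOL-power calculations.

## The model

The eye is a Gullstrand simplified (two-thin-lens) eye. Referring the
cornea of power $F_c$ to the IOL plane a distance $d$ (the effective lens
position, ELP) behind it gives the equivalent corneal power

$$F_e = \frac{n_{ah} F_c}{n_{ah} - d\,F_c}, \qquad n_{ah} = 1.336 .$$

Emmetropia requires the total power at the IOL plane to focus parallel
light on the retina through silicone oil ($n_{SO} = 1.403$), so the
required IOL power is

$$F_{IOL} = \frac{n_{SO}}{AL - ELP} - \frac{n_{ah} F_c}{n_{ah} - ELP \cdot F_c}$$

with the axial length $AL$ and $ELP$ in metres. The ELP comes from the
Haigis linear model $ELP = a_0 + a_1 \cdot AC + a_2 \cdot AL$ (anterior
chamber depth $AC$; per-lens constants $a_i$, with an A-constant fallback
conversion), and axial lengths above 26 mm are first passed through the
Wang-Koch linear adjustment. A stepwise reduced-vergence ray propagation
is included as an independent oracle for the closed form, and a numerical
inverse recovers the ELP implied by any (AL, K, power) triple.

The validation pipeline reconstructs the clinically required power as
*implanted power + postoperative spectacle sphere* and compares it with
the formula's prediction: mean absolute error, error-band counts, paired
t-test, and the two-way consistency intraclass correlation ICC(3,1) with
its F-based confidence interval — computed from the two clinical cohorts
packaged with the library (13 oil-dependent eyes; 19 first-stage
implantation eyes).

## Worked example

```sh
$ soiol calc --al 23.5 --k 43.5 --acd 3.0 --a-constant 118
constants          cli (a0=1.2771, a1=0.4, a2=0.1; A-constant conversion)
ELP                4.827 mm
adjusted AL        23.500 mm
SO IOL power       23.52 D
water IOL power    19.94 D
SO-water delta     3.59 D
```

For this eye the formula asks for a 23.52 D lens while a water-filled-eye
calculation with the same ELP would ask for 19.94 D — the 3.59 D delta is
exactly $(n_{SO}-n_{ah})/(AL-ELP)$ and falls inside the empirical
"add 3–5 D" range.

Validating against the packaged oil-dependent cohort:

```sh
$ python examples/validate_cohort.py
n = 13 silicone-oil-dependent eyes
theoretical power: 24.96 +/- 3.29 D
clinical required: 24.02 +/- 4.14 D
MAE:               1.66 +/- 2.09 D
error bands [0,.5),[.5,1),[1,1.5),[1.5,2),[2,inf): (4, 0, 5, 2, 2)
ICC(3,1) = 0.771, 95% CI (0.405, 0.924)
paired t: t = 1.34, p = 0.205

excluding the two flat-cornea eyes (errors >= 2 D): MAE 0.83 +/- 0.62 D over 11 eyes
```

The formula and the clinical reconstruction agree strongly (ICC 0.771, no
significant paired difference); both large errors come from the two eyes
with corneas flatter than 42 D, where Haigis-style ELP prediction is known
to struggle.

Other entry points: `soiol validate group_a --exclude-flat-cornea 42`,
`soiol batch`, `soiol constants`, `soiol synth`, and the scripts in
`examples/` (single-eye calculation, implied-ELP sweep, synthetic-cohort
pipeline check).

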