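"""Reproduce the clinical validation statistics from the packaged cohort.

Loads the 13 silicone-oil-dependent eyes, reconstructs the clinically
required IOL power (implanted power + postoperative spectacle sphere),
and prints the group-level agreement statistics between the formula's
predictions and the clinical reconstruction.
"""

from soiol import (
    OutcomeRecord,
    load_table,
    mae,
    prediction_errors,
    summarize_group,
)

outcomes = [OutcomeRecord.from_biometry(r) for r in load_table("group_a")]
report = summarize_group(outcomes)

print(f"n = {report.n} silicone-oil-dependent eyes")
print(f"theoretical power: {report.mean_theoretical:.2f} +/- {report.sd_theoretical:.2f} D")
print(f"clinical required: {report.mean_clinical:.2f} +/- {report.sd_clinical:.2f} D")
print(f"MAE:               {report.mae:.2f} +/- {report.sd_abs_error:.2f} D")
print(f"error bands [0,.5),[.5,1),[1,1.5),[1.5,2),[2,inf): {report.band_counts}")
print(f"ICC(3,1) = {report.icc:.3f}, 95% CI ({report.icc_ci_low:.3f}, {report.icc_ci_high:.3f})")
print(f"paired t: t = {report.t_statistic:.2f}, p = {report.p_two_sided:.3f}")

# The two large errors come from the two flat-cornea eyes (K < 42 D).
table = prediction_errors(outcomes)
kept = [o for o, e in zip(outcomes, table.abs_error_d) if e < 2.0]
m, sd = mae(prediction_errors(kept))
print(f"\nexcluding the two flat-cornea eyes (errors >= 2 D): "
      f"MAE {m:.2f} +/- {sd:.2f} D over {len(kept)} eyes")
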