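"""Invert the formula: what lens position do the printed powers imply?

For each oil-dependent eye, solve for the effective lens position (ELP)
at which the vergence formula reproduces that eye's recorded theoretical
IOL power. A physiologically plausible ELP (roughly 3-8 mm behind the
cornea) indicates the printed power is consistent with some Haigis-like
constant set; an implausible one flags an inconsistent row.
"""

from soiol import implied_elp, load_table

print("eye    AL (mm)   K (D)   power (D)   implied ELP (mm)")
for r in load_table("group_a"):
    elp_mm = implied_elp(
        r.axial_length_mm / 1000.0, r.mean_k_d, r.theoretical_power_d
    ) * 1000.0
    flag = "" if 3.0 < elp_mm < 8.0 else "   <- implausible"
    print(f"{r.patient_id}   {r.axial_length_mm:6.2f}   {r.mean_k_d:5.2f}   "
          f"{r.theoretical_power_d:7.2f}   {elp_mm:10.3f}{flag}")
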