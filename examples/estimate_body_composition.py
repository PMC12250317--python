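"""Estimate one athlete's body composition with several equations.

Builds a single measured subject (skinfolds in mm, girths in cm), runs a
selection of prediction equations, and prints the estimates.  The spread
across equations — several percentage points of body fat for the same
tape-and-caliper measurements — is exactly why these equations need
validation against a reference method before being trusted in a new
population.
"""

from anthroagree import AnthroProfile, estimate_bd, bd_to_fp, estimate_fp, estimate_fm, estimate_lm

athlete = AnthroProfile(
    subject_id="demo-01",
    sex="male",
    age=29.0,
    race="hispanic",
    body_weight_kg=72.4,
    height_cm=171.0,
    skinfolds_mm={"BI": 6.2, "TR": 10.5, "SS": 16.0, "SI": 20.4, "SSP": 13.0, "AB": 22.8, "TH": 12.1, "C": 8.4},
    circumferences_cm={"Ac": 33.0, "FAc": 27.0, "THc": 56.0, "Cc": 37.5, "CHc": 101.0, "WC": 92.0, "HC": 99.0},
    diameters_cm={"WD": 5.6, "FD": 9.5},
    amputation_level="transtibial",
)

bd = estimate_bd("durnin_womersley", athlete)
print(f"Body density (Durnin & Womersley four-fold):    {bd:.4f} g/ml")
print(f"  -> fat %  via Siri:                            {bd_to_fp('siri', bd):5.2f} %")
print(f"  -> fat %  via Brozek:                          {bd_to_fp('brozek', bd):5.2f} %")
print(f"Fat % (Hastuti, triceps+suprailiac+sex):        {estimate_fp('hastuti', athlete):5.2f} %")
print(f"Fat % (kinanthropometric 5-way fractionation):  {estimate_fp('isak5_fp', athlete):5.2f} %")
print(f"Fat mass (Lee DH):                              {estimate_fm('lee_dh_fm', athlete):5.2f} kg")
print(f"Lean mass (Chien):                              {estimate_lm('chien', athlete):5.2f} kg")
print(f"Lean mass (Olshvang):                           {estimate_lm('olshvang', athlete):5.2f} kg")
print()
print("Different equations disagree by several % body fat on the same subject;")
print("choosing one requires a method-agreement validation against DXA.")
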