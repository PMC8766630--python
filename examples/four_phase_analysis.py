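"""Analyze a 4-phase rhinomanometry cycle and classify the obstruction.

Builds a noisy synthetic respiration cycle with a known resistance,
recovers the effective resistance, and places it on the five-class
obstruction scale; also shows the parallel combination of two sides.
"""

from rhinoflow.fourphase import (
    analyze,
    classify_resistance,
    combined_log_resistance,
)
from rhinoflow.phantoms import make_4pr_waveform

rec, _ = make_4pr_waveform(r_true=0.30, cycle_s=4.0, peak_flux=400.0,
                           noise=0.05, seed=7)
res = analyze(rec)
print(f"R_eff  = {res.r_eff:.3f} Pa s/cm3   (truth: 0.300)")
print(f"LR1    = {res.lr_eff_1:.3f}          -> class {res.obstruction_class} "
      f"({res.class_label})")
print(f"VR insp = {res.vr_insp:.3f}, VR exp = {res.vr_exp:.3f} Pa s/cm3")

# total nose from two sides measured separately (parallel resistors)
lr2 = combined_log_resistance(0.45, 0.62)
cls = classify_resistance(lr2, sided="two")
print(f"two-sided LR2 = {lr2:.3f} -> class {cls.number} ({cls.label})")
# The effective resistance is recovered within ~1% despite 5% pressure
# noise; the log scale and class are what a clinician reads off.
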