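"""Fluorescence-polarization Kd fitting and linker-length additivity.

Simulates a plate titration (protein two-fold diluted from 200 uM, labelled
RNA at 0.2 uM), fits the exact ligand-depletion isotherm, and computes the
affinity-gain ratios of the printed poly-C linker series.
"""

from starbind import TitrationSpec, additivity_ratio, fit_kd, generate_fp_titration

titration = generate_fp_titration(
    TitrationSpec(true_kd=5.0, f_free=50.0, f_bound=250.0, noise_sd=4.0, seed=5)
)
fit = fit_kd(titration, model="quadratic")
print(f"simulated titration, true Kd 5.0 uM, 2% noise:")
print(f"  fitted Kd = {fit.kd:.2f} +/- {fit.standard_error_kd:.2f} uM "
      f"(f_free {fit.f_free:.0f}, f_bound {fit.f_bound:.0f}, "
      f"residual sd {fit.residual_sd:.1f})")
print("  -> the depletion-aware fit recovers the dissociation constant\n")

# printed dissociation constants (uM) for RNAs with two UAAA sites joined by
# poly-C linkers: affinity jumps once the linker exceeds ~15 nt
tstar_star = {5: 5.9, 10: 7.0, 15: 6.7, 20: 2.1, 25: 1.4, 30: 1.7}
sam68_qua1kh = {5: 42.7, 10: 37.3, 15: 26.3, 20: 8.4, 25: 4.0, 30: 5.0}

print("additivity ratios (Kd short-linker / Kd long-linker):")
print(f"  T-STAR STAR   C15 vs C25: "
      f"{additivity_ratio(tstar_star[15], tstar_star[25]):.2f}")
print(f"  Sam68 QUA1-KH C15 vs C20: "
      f"{additivity_ratio(sam68_qua1kh[15], sam68_qua1kh[20]):.2f}")
print("  -> ratios well above 1 for linkers > 15 nt: the dimer engages both\n"
      "     UAAA sites at once, the avidity signature of bipartite binding")
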