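"""Fitting SPR and ITC binding data with known ground truth.

Generates a noisy single-cycle sensorgram, a steady-state series, and a
reverse-titration ITC isotherm at the measured p21 design, then fits each
with its model and compares the recovered parameters to the truth.
"""

from pipflank import (
    gen_itc,
    gen_sensorgram,
    gen_steady_state,
    itc_fit,
    spr_kinetic_fit,
    spr_steady_state_fit,
    thermodynamics,
)

# single-cycle kinetics at the p21-like rates
truth_kd = 0.14 / 1.7e6
s = gen_sensorgram(kon=1.7e6, koff=0.14, noise_sigma=2.0, seed=11)
rec = spr_kinetic_fit(s, ligand_id="p21")
print("SPR single-cycle kinetics (truth kon=1.7e6, koff=0.14):")
print(f"  kon  = {rec.kon:.3g} /(M s), koff = {rec.koff:.3g} /s")
print(f"  KD   = {rec.kd * 1e9:.1f} nM (truth {truth_kd * 1e9:.1f} nM)")

# steady state at a weak-binder affinity
ss = gen_steady_state(kd=3.0e-6, rel_noise=0.01, seed=11)
rec2, rmax = spr_steady_state_fit(ss, ligand_id="MSH6-like")
print(f"\nSPR steady state (truth KD = 3.0 uM): "
      f"fitted KD = {rec2.kd * 1e6:.2f} uM, Rmax = {rmax:.0f} RU")

# reverse-titration ITC at the measured design
exp = gen_itc(n=3.0, kd=67e-9, dh=-230e3, rel_noise=0.02, seed=11)
rec3 = itc_fit(exp, ligand_id="p21")
print(f"\nITC one set of sites (truth n=3, KD=67 nM, dH=-230 kJ/mol):")
print(f"  n = {rec3.n:.2f}, KD = {rec3.kd * 1e9:.0f} nM, "
      f"dH = {rec3.dH / 1e3:.0f} kJ/mol")
dg, mtds = thermodynamics(rec3.kd, rec3.dH)
print(f"  dG = {dg / 1e3:.1f} kJ/mol, -TdS = {mtds / 1e3:.0f} kJ/mol "
      "(binding is enthalpy-driven with an entropic penalty)")
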