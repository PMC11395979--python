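"""Simulate a synthetic two-class aorta cohort and inspect its structure.

Generates 60 records (30 normal, 30 coarctation) with class-conditional
landmark diameters and mass-balance hemodynamics, then prints the class
means of the discriminating diameters and checks flow conservation.
"""

import aortameta as am

cfg = am.CohortConfig(seed=7)
cohort = am.generate_cohort(cfg)
am.write_cohort_csv(cohort, "cohort_seed7.csv")

print(f"generated {len(cohort)} records (config hash {cfg.hash()})")
print("\nclass means of the most class-separated diameters (mm):")
print(cohort.groupby("label")[["D0", "D3", "DBCA", "D5"]].mean().round(2))

# with the noise switched off, volume flow is conserved exactly:
# v(P1) D1^2 = sum over outlets of v Dk^2
silent = am.generate_cohort(cfg.with_noise_scale(0.0))
residual = silent.apply(am.continuity_residual, axis=1).max()
print(f"\nmax continuity residual at zero noise: {residual:.2e}"
      " (machine precision)")

# D0 (minimal descending diameter) separates the classes: in coarctation
# the isthmus narrows to a fraction of the normal caliber, which is what
# every downstream classifier ultimately exploits.
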