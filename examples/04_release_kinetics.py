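"""Discriminate release-kinetics models on a simulated dissolution profile.

A square-root-of-time (Higuchi) release curve with 2% measurement noise is
generated, all three candidate laws are fitted, and T50 — the time to 50%
release — is solved from the winning model.
"""

from formulab import fit_release_models, t50
from formulab.simulate import gen_release_profile

profile = gen_release_profile("higuchi", k=20.0, noise_pct=2.0, seed=1)
print("time (h):", profile.time_h.tolist())
print("release (%):", [round(float(q), 1) for q in profile.cumulative_pct])

result = fit_release_models(profile)
for name, fit in result.fits.items():
    print(f"{name:12s} rate {fit.rate:8.4f}  intercept {fit.intercept:7.3f}  "
          f"R² {fit.r2:.4f}")
print(f"\nBest model: {result.best_model} (truth was Higuchi, k = 20 %/√h)")
print(f"T50 = {t50(result):.2f} h  (noiseless truth: (50/20)² = 6.25 h)")
print("Higuchi kinetics indicate diffusion-controlled release from the")
print("micelle core with no burst (small intercept).")
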