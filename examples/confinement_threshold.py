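"""Fit the confinement-dependent instability threshold I = a * alpha_eff.

Generates a threshold-intensity dataset over square activation regions
(L = W = 50..500 um, chamber height 100 um) with 5% noise from the
geometric bound

    alpha_eff = pi^2 L^2 (1/L^2 + 1/W^2 + 1/H^2)^2   (short regions)
              = 4 pi^2 (1/W^2 + 1/H^2)               (long regions)

and recovers the activity coefficient a, alongside the phenomenological
1/L^2 + C comparison fit.
"""

import optoflow as of

geometries = [(L, L, 100.0) for L in (50, 100, 150, 200, 250, 300, 400, 500)]
data = of.gen_threshold_dataset(a=1.17, geometries=geometries,
                                rel_noise=0.05, seed=6)

fit = of.fit_activity_coefficient(data)
generic = of.fit_generic_scaling(data)

print(data.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(f"activity coefficient a : {fit.a:.3f} +- {fit.se:.3f}  (programmed 1.17)")
print(f"generic 1/L^2 + C fit  : gA = {generic.gA:.3g}, gC = {generic.gC:.3g}")
print(f"predicted threshold at L=W=300, H=100 um : "
      f"{of.predict_threshold(300, 300, 100, fit):.3f} uW/mm^2")
print()
print("a converts the geometric instability bound alpha_eff (um^-2) into")
print("the illumination intensity needed to cross it; the threshold stops")
print("depending on L once 1/L^2 < 1/W^2 + 1/H^2.")
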