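"""Paradoxical activation from conformational autoinhibition alone.

Builds the autoinhibition (CA) model at the default cellular parameters
(K_A = 10, K_dim = K_d = 0.1 uM, [RAF] = 0.04 uM), sweeps the inhibitor
concentration, and prints the PA summary: active RAF rises above its
drug-free baseline at intermediate doses before full inhibition at high
doses.
"""

from rafpa import DoseGrid, ModelParams, Variant, dose_response, pa_metrics

params = ModelParams(K_A=10.0, K_dim=0.1, K_d=0.1, raf_total=0.04,
                     variant=Variant.CA)
grid = DoseGrid.log(1e-4, 1e2, 25)

dr = dose_response(params, grid)
m = pa_metrics(dr)

print(f"baseline active fraction : {m.baseline:.4f}")
print(f"peak active fraction     : {m.peak:.4f} at {m.peak_dose_uM:.3g} uM")
print(f"PA fold change           : {m.pa_fold_change:.3f}")
lo, hi = m.pa_range_uM
print(f"PA range                 : {lo:.3g} .. {hi:.3g} uM")
print(f"has PA                   : {m.has_pa}")
# The fold change is peak/baseline activity; the PA range is the dose
# window in which the drug *increases* RAF signaling — its upper end is
# where activity passes back through the baseline.
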