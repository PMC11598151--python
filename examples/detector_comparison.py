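"""Compare the classic matched filter, the whitened matched filter (OMF) and
the WLS-smoothed variant (OMF-WLS) across noise levels.

The edge-preserving smoothing pays off most on noisy scenes with canopy
gaps: it averages away isolated misclassified pixels inside coherent target
patches while keeping patch boundaries sharp.
"""

from omfwls import SceneSpec, sweep

specs = [
    SceneSpec(rows=128, cols=128, noise_sigma=sigma, gap_fraction=0.2, seed=seed)
    for sigma in (0.02, 0.05, 0.1)
    for seed in range(3)
]
df = sweep(specs)
table = df.groupby(["noise_sigma", "detector"])["kappa"].median().unstack()
print("median Kappa by per-band noise sigma (3 seeds each):")
print(table[["mf", "omf", "omf_wls"]].round(4))
print("\nColumns: classic matched filter, whitened MF, whitened MF + WLS;")
print("the omf_wls column should dominate omf as noise grows.")
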