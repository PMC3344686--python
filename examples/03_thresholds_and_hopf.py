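"""Critical parameter values: where cancer becomes impossible, where normal
cells are displaced, and where sustained oscillations live.

All detections are bisections: on the interior maximum of the root balance
(saddle-node folds), on branch/bound crossings (displacement), on the
leading complex eigenvalue pair (oscillation onset), and on simulated
attractor verdicts (cycle exit).
"""

import angiodyn as ad

p = ad.load_preset("fixed")

b2, t2 = ad.saddle_node_threshold(p, "beta2", (0.04, 0.06))
print(f"beta2 fold: beta2_th = {b2:.4e}  (branches collide at T = {t2:.4f})")
print("  -> stronger suppression of tumour cells by normal tissue than this")
print("     makes every pulse regress, whatever its size")

g, tg = ad.saddle_node_threshold(p, "gamma", (1e-4, 1e-3))
print(f"gamma fold: gamma_th = {g:.4e}  (T = {tg:.4f})")

e, te = ad.saddle_node_threshold(p.replace(gamma=0.0), "eps", (0.01, 0.1))
print(f"eps fold (vasculogenesis, gamma=0): eps_th = {e:.4e}  (T = {te:.4f})")

b1c, tcc = ad.critical_beta1(p)
print(f"displacement: beta1_c = {b1c:.4e}, pinned tumour level TC_c = {tcc:.4f}")
print("  -> beyond beta1_c the tumour excludes the normal cells entirely (C=0)")

(g1c, t1c, _), = ad.hopf_points(p, (0.02, 0.026))
g2c, t2c = ad.limit_cycle_exit(p, (0.025, 0.0253))
print(f"oscillations: onset gamma_1c = {g1c:.4e} (T = {t1c:.4f}),")
print(f"              cycle exit gamma_2c = {g2c:.4e} (T = {t2c:.4f})")
print("  -> between the two, trajectories orbit the (unstable) tumour state")
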