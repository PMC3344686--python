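"""Enumerate the steady states of the model and classify their stability.

The non-trivial tumour levels are the feasible roots of the quartic balance
f(T) = g1(T) + g2(T) inside (0, min(TE, TA)); the smaller root is the
unstable break-point whose stable manifold separates the basins.
"""

import angiodyn as ad

params = ad.load_preset("fixed")

cons = ad.constraints(params)
print(
    f"feasibility bounds: TC={cons.TC}, TE={cons.TE}, TA={cons.TA}, Tg={cons.Tg}"
)

points = [ad.trivial_equilibrium(params)] + ad.find_cancer_equilibria(params)
for pt in points:
    rep = ad.stability_report(params, pt)
    coords = ", ".join(f"{v:.2f}" for v in pt.coords)
    lead = rep.eigenvalues[0]
    print(
        f"{pt.label:>8}: ({coords})  {rep.classification:<13} "
        f"leading eigenvalue {lead.real:+.3f}{lead.imag:+.3f}i per day"
    )

print(
    "\nThe cancer-free state and the large tumour state are both attractors"
    "\n(bistability); the break-point in between is the watershed."
)
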