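"""Fluctuation geometry at coexistence under three drift-compatible closures.

All three channel representations share the deterministic drift, but only
the coupled ones (bernoulli, effective) carry the same-event anticorrelation
of prey loss and predator gain: a12 < 0 tilts the covariance ellipse
downward, while the split (diagonal-noise) comparator is axis-aligned.
"""

from rmstoch import (
    ModelParams,
    build_channels,
    covariance_ellipse,
    diffusion_matrix,
    equilibria,
)

params = ModelParams(m=1.5, c=0.4, k=2.0, e=1.0, omega=200.0)
k3 = equilibria(params).K3
print(f"K3 = ({k3[0]:.4f}, {k3[1]:.4f}), Omega = {params.omega:g}\n")

for closure in ("effective", "bernoulli", "split"):
    cs = build_channels(params, closure)
    rep = diffusion_matrix(cs, k3)
    ell = covariance_ellipse(rep.a, k3)
    a = rep.a
    print(f"{closure:>9}:  a12 = {a[0, 1]:+.3e}   rho(K3) = {rep.rho:+.4f}   "
          f"ellipse tilt = {ell.angle_deg:+6.2f} deg")

print(
    "\nNegative rho means predator and prey fluctuations are anticorrelated "
    "through the shared predation-conversion event; the split closure erases "
    "this (tilt 0) despite having the identical drift."
)
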