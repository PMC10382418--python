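"""Frozen-Gaussian matrix elements between trajectory basis functions.

Creates a reproducible random pair of TBFs and prints the closed-form
overlap, nuclear-derivative and kinetic-energy brakets that enter the
coupled amplitude equations.  The diagonal elements have simple physical
readings: unit norm, i times the momentum, and the kinetic energy plus the
zero-point term alpha/(2M) per coordinate.
"""

import numpy as np

from multispawn import (
    centroid,
    derivative_element,
    kinetic_element,
    overlap,
    random_tbf_pair,
)

a, b = random_tbf_pair(2, seed=7)
masses = np.array([1.0, 2.0])

print("TBF a: R =", np.round(a.R, 3), " P =", np.round(a.P, 3),
      " alpha =", np.round(a.alpha, 3))
print("TBF b: R =", np.round(b.R, 3), " P =", np.round(b.P, 3),
      " alpha =", np.round(b.alpha, 3))

print(f"\n<a|a>            = {overlap(a, a):.6f}  (normalization)")
print(f"<a|b>            = {overlap(a, b):.6f}")
print(f"<a|d/dR_0|a>     = {derivative_element(a, a, 0):.6f} "
      f"(equals i P_0 = {1j * a.P[0]:.6f})")
print(f"<a|T|a>          = {kinetic_element(a, a, masses):.6f} "
      f"(= sum (P^2 + alpha)/2M = "
      f"{((a.P**2 + a.alpha) / (2 * masses)).sum():.6f})")
print(f"<a|T|b>          = {kinetic_element(a, b, masses):.6f}")
print("centroid(a, b)   =", np.round(centroid(a, b), 4),
      " (width-weighted midpoint: the electronic-structure evaluation "
      "point of the pair)")
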