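"""Closed-form material functions of the fractional Drude medium.

Evaluates susceptibility, permittivity and wave vector for the normalized
parameter set (wp = 0.3, gamma_alpha = 1, gamma_beta = 0.1) and shows the
Drude limit alpha = beta = 1 against the classical formula.
"""
import numpy as np

from fracdrude import (FractionalDrudeMedium, permittivity, susceptibility,
                       wavevector)

drude = FractionalDrudeMedium(omega_p_sq=0.09, gamma_alpha=1.0,
                              gamma_beta=0.1, alpha=1.0, beta=1.0)
frac = FractionalDrudeMedium(omega_p_sq=0.09, gamma_alpha=1.0,
                             gamma_beta=0.1, alpha=0.8, beta=0.8)

print("omega     chi(Drude)              chi(alpha=beta=0.8)")
for omega in (0.1, 0.3, 1.0):
    c1, c2 = susceptibility(drude, omega), susceptibility(frac, omega)
    print(f"{omega:5.2f}  {c1.real:+8.4f}{c1.imag:+8.4f}i   "
          f"{c2.real:+8.4f}{c2.imag:+8.4f}i")
print("At omega = wp the classical value is exactly -0.9 + 0.3i;")
print("the fractional orders reshape both dispersion and absorption.")

lossless = FractionalDrudeMedium(omega_p_sq=0.09, gamma_beta=0.0)
k = wavevector(lossless, 0.1)
print(f"\nBelow wp (omega=0.1, lossless): k = {k:.4f} -> purely imaginary,")
print("an evanescent wave in the negative-permittivity region,")
print(f"eps = {permittivity(lossless, 0.1).real:.4f}")
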