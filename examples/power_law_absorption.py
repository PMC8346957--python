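"""Power-law wave absorption with a tunable exponent.

Above the plasma frequency the attenuation Im k follows omega^(beta-3);
the beta order dials the exponent, the alpha order flattens it.
"""
import numpy as np

from fracdrude import (FractionalDrudeMedium, imk_asymptotic_exponent,
                       imk_spectrum_numeric)

omega = np.logspace(np.log10(0.3e-1), np.log10(0.3e4), 400)
for alpha, beta in ((1.0, 1.0), (1.0, 0.5), (0.01, 1.0)):
    med = FractionalDrudeMedium(omega_p_sq=0.09, gamma_beta=0.1,
                                alpha=alpha, beta=beta)
    _, slope = imk_spectrum_numeric(med, omega)
    note = ""
    if alpha == 1.0:
        note = f"(predicted beta-3 = {imk_asymptotic_exponent(med):+.1f})"
    print(f"alpha={alpha:4} beta={beta:4}: fitted log-log slope of Im k "
          f"= {slope:+.3f} {note}")
print("alpha -> 0 makes the absorption nearly frequency-flat, the")
print("phenomenology seen for waves in soft biological tissue.")
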