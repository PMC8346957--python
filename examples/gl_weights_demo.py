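"""Truncated Grunwald-Letnikov weights and a fractional derivative.

Builds the weight table for order 0.5, differentiates a sampled harmonic
and compares with the analytic rule D^a e^{iwt} = (iw)^a e^{iwt}.
"""
import numpy as np

from fracdrude import SampledSignal, gl_derivative, gl_weights

table = gl_weights(0.5, 8)
print("GL weights, order 0.5:", np.array2string(table.weights, precision=6))
print("  -> w_0 = 1; the negative algebraic tail is the operator's memory")

t = np.arange(4001) * 0.01
got = gl_derivative(SampledSignal(np.exp(1j * t), 0.01), 0.5)
want = (1j) ** 0.5 * np.exp(1j * t[-1])
print(f"D^0.5 e^(it) at t={t[-1]:.2f}: numeric {got:.6f}, "
      f"analytic {want:.6f}")
print(f"relative error {abs(got - want) / abs(want):.2e} "
      "(truncation + startup transient)")
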