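"""Dynamic mode decomposition on a known linear system.

On data generated by y_{t+1} = A y_t the decomposition is exact: the fitted
eigenvalues equal the spectrum of A, and each eigenvalue's complex argument
gives the mode's oscillation frequency f = Im(ln lambda) / (2 pi dt).
"""

import numpy as np

from swarmdmd import fit_dmd, linear_fixture, reconstruct

theta = np.pi / 8  # rotation per step
A = 0.95 * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
seq, truth = linear_fixture(A, tau=100, dt=0.1, seed=0)

result = fit_dmd(seq)
print("true eigenvalues:  ", np.round(np.sort_complex(truth), 6))
print("fitted eigenvalues:", np.round(np.sort_complex(result.eigenvalues), 6))
print(f"mode frequency: {abs(result.frequencies[0]):.4f} Hz "
      f"(analytic {theta / (2 * np.pi * 0.1):.4f} Hz)")

recon = reconstruct(result, 0.0).real
print(f"reconstruction of the first snapshot: {recon}  (data: {seq.values[:, 0]})")
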