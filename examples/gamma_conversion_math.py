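"""The moment-matching conversion, in isolation.

Given fitted gamma parameters (shape alpha, mean lifetime tau_gamma), the
biexponential parameters are recovered by equating raw moments: two moments
when the major lifetime tau1 is known, three when it is free.  The
converted mixture reproduces the gamma moments exactly — that identity is
the whole estimator.
"""

from decayfit import (
    GammaParams,
    biexp_moments,
    convert_three_moment,
    convert_two_moment,
    gamma_moments,
)

g = GammaParams(alpha=0.8, tau_gamma=1200.0)

print("two-moment conversion (tau1 = 1500 ps known):")
res = convert_two_moment(g, tau1=1500.0)
print(f"  c_hat = {res.raw_c:.6f}, tau2_hat = {res.raw_tau2:.3f} ps")
for k in (1, 2):
    print(
        f"  moment k={k}: gamma {gamma_moments(g, k):.6g}  "
        f"biexp {biexp_moments(res.biexp, k):.6g}"
    )

print("\nthree-moment conversion (tau1 free):")
res3 = convert_three_moment(GammaParams(alpha=0.5, tau_gamma=1000.0))
print(
    f"  c_hat = {res3.raw_c:.6f}, tau1_hat = {res3.raw_tau1:.3f} ps, "
    f"tau2_hat = {res3.raw_tau2:.3f} ps"
)
for k in (1, 2, 3):
    got = biexp_moments(res3.biexp, k)
    want = gamma_moments(GammaParams(0.5, 1000.0), k)
    print(f"  moment k={k}: gamma {want:.6g}  biexp {got:.6g}")
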