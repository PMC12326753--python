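"""Sensitivity of the log-determinant approximation to its tuning knobs.

Sweeps each of n_samples, n_lanczos, n_int and n_cocg while the others stay
at their defaults, reporting the mean relative difference to the exact
log|C| with a 95% confidence interval across probe seeds.
"""

import mclogdet as mc

spec = mc.SimSpec(
    n_founders=120, n_generations=5, n_offspring=180, n_sires=15,
    n_snp=500, prop_genotyped=0.3, n_cg=15, seed=30,
    true_varcomps={"animal": 0.3, "residual": 0.7},
)
frame = mc.simulate_dataset(spec)
C = mc.mme_operator(frame, {"animal": 0.3, "residual": 0.7})
exact = mc.exact_logdet_ldl(C.explicit_sparse())

df = mc.sensitivity_sweep(C, exact, n_seeds=3)
print(f"exact log|C| = {exact:.2f}  ({C.n} equations)\n")
print(df.to_string(index=False, float_format=lambda x: f"{x: .2e}"))
# Reading the table: accuracy saturates once n_lanczos resolves the extreme
# eigenvalues and n_int/n_cocg resolve the quadrature and its inner solves;
# past that point only n_samples (probe noise) limits the error.
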