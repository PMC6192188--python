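"""Demographic expansion: mismatch distribution, neutrality tests, dating.

Fits the sudden-expansion model to the pairwise-difference histogram,
checks fit by parametric bootstrap (SSD, raggedness), computes Tajima's
D and Fu's Fs, and converts the fitted tau into an expansion time.
"""

import numpy as np

from hapgeo import (
    bootstrap_gof,
    collapse_haplotypes,
    expansion_time,
    fit_sudden_expansion,
    fus_fs,
    make_study_fixture,
    mismatch_from_counts,
    raggedness,
    tabulate_by_population,
    tajimas_d,
)

fx = make_study_fixture("cpDNA")
col = collapse_haplotypes(fx.alignment)
table = tabulate_by_population(col, fx.popmap)
L = fx.alignment.L

hist = mismatch_from_counts(table.total_counts, col.distances)
print("observed mismatch frequencies:", np.round(hist, 4))
fit = fit_sudden_expansion(hist)
print(f"sudden-expansion fit: tau={fit.tau:.3f}  theta0={fit.theta0:.4f}  "
      f"theta1={fit.theta1:.2f}  SSD={fit.ssd:.4f}  HRag={raggedness(hist):.4f}")

gof = bootstrap_gof(hist, fit, table.n_total, n_boot=200, seed=5)
print(f"parametric bootstrap: p(SSD)={gof.p_ssd:.3f}  "
      f"p(HRag)={gof.p_raggedness:.3f}  (p > 0.05: expansion model not rejected)")

n, S = table.n_total, col.distances.n_segregating
k_hat = float(np.dot(np.arange(len(hist)), hist))
D, pD = tajimas_d(n, S, k_hat)
Fs = fus_fs(n, len(col.haplotype_ids), k_hat)
print(f"Tajima's D={D:.3f} (p={pD:.3f});  Fu's Fs={Fs:.3f}")

# date the fitted expansion: mu per site per year, locus length, generation time
est = expansion_time(fit.tau, mu=2e-9, k=L, g=10)
print(f"expansion time: {est.t_generations:,.0f} generations "
      f"= {est.t_years/1e6:.2f} Myr (u={est.u:.3e} per generation)")
print("\nA smooth unimodal mismatch distribution with non-significant SSD "
      "is the classic\nsignature of a past demographic expansion; tau/2u "
      "converts its mode into time.")
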