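"""Coalescent simulation: migration shapes differentiation.

Simulates island-model datasets at three migration rates and shows the
monotone decline of GST with gene flow -- the calibration logic behind
the package's stochastic tests.
"""

import numpy as np

from hapgeo import (
    SimSpec,
    collapse_haplotypes,
    permut_statistics,
    simulate_dataset,
    tabulate_by_population,
)

for m in (0.01, 0.1, 1.0):
    gsts = []
    for rep in range(20):
        spec = SimSpec(sample_sizes=[10] * 4, theta=1.0, migration=m, L=20_000)
        aln, pm = simulate_dataset(spec, seed=100 * rep + int(m * 1000))
        col = collapse_haplotypes(aln)
        if len(col.haplotype_ids) < 2:
            continue
        table = tabulate_by_population(col, pm)
        res = permut_statistics(table)
        if np.isfinite(res.gst):
            gsts.append(res.gst)
    print(f"migration rate {m:>5}: mean GST = {np.mean(gsts):.3f}  "
          f"({len(gsts)} polymorphic replicates)")

print("\nLower migration -> stronger drift per deme -> higher GST; the same "
      "machinery\n(with a stepwise size change) powers the mismatch-distribution "
      "bootstrap.")
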