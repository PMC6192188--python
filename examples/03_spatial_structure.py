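"""Spatial structure: SAMOVA grouping, AMOVA decomposition, isolation by distance.

SAMOVA searches partitions of populations into K geographically seeded
groups maximising the among-group fixation index Phi_CT; the selected K
feeds a three-level AMOVA.  A Mantel test asks whether genetic and
geographic distances correlate.
"""

from hapgeo import (
    amova,
    collapse_haplotypes,
    fct_plateau,
    geographic_distance_matrix,
    make_study_fixture,
    mantel_test,
    pairwise_phist,
    samova_scan,
    tabulate_by_population,
)

fx = make_study_fixture("cpDNA")
col = collapse_haplotypes(fx.alignment)
table = tabulate_by_population(col, fx.popmap)
coords = fx.popmap.coordinates()

scan = samova_scan(table.counts, col.distances, coords, k_range=range(2, 7),
                   n_starts=8, n_proposals=1500, seed=7)
traj = {k: float(r.fct) for k, r in scan.items()}
print("Phi_CT by K:", {k: round(f, 4) for k, f in traj.items()})
k_sel = fct_plateau(traj)
best = scan[k_sel]
print(f"selected K={k_sel}; groups:", [sorted(g) for g in best.partition])

pops = [fx.popmap.assignments[i] for i in fx.alignment.ids]
res = amova(col.indices(), pops, col.distances, groups=best.group_map(),
            n_perm=1000, seed=11)
print("\nAMOVA:")
print(res.table.round(4).to_string())
print("Phi:", {k: round(float(v), 4) for k, v in res.phi.items()})
print("p:", {k: round(v, 4) for k, v in res.p_values.items()})

gen = pairwise_phist(table.counts, col.distances, linearized=False)
geo = geographic_distance_matrix(coords, order=table.populations)
mt = mantel_test(gen, geo, n_perm=9999, seed=3)
print(f"\nMantel (Phi_ST vs great-circle km): r={mt.r:.3f}, p={mt.p_value:.3f}")
print("Most variance sits among SAMOVA groups while the Mantel correlation "
      "stays\nnon-significant: structure is patchy rather than a smooth cline.")
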