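"""Analysis of molecular variance (AMOVA) on haplotype distances.

The squared molecular distance between two individuals is the
substitution count between the haplotypes they carry, and sums of
squares at each hierarchical level come from the pairwise identity
SS(set) = sum_{x<y in set} delta^2 / |set|.  Variance components are
obtained from the standard nested moments equations with
unequal-sample-size coefficients, giving the Phi-statistics

    Phi_CT = Va / V          (among groups)
    Phi_SC = Vb / (Vb + Vc)  (among populations within groups)
    Phi_ST = (Va + Vb) / V   (among populations overall)

with V = Va + Vb + Vc.  Significance uses the per-statistic permutation
schemes of Excoffier et al.: Phi_ST permutes individuals among
populations, Phi_SC permutes individuals among populations within their
group, and Phi_CT permutes whole populations among groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .haplotypes import DistanceMatrix

__all__ = ["AmovaResult", "amova", "pop_pairwise_sums"]


@dataclass
class AmovaResult:
    table: pd.DataFrame                 # rows: variance levels + Total
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int | None = None
    seed: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def variance_components(self) -> pd.Series:
        return self.table["variance"].drop("Total")

    @property
    def percentages(self) -> pd.Series:
        return self.table["pct"].drop("Total")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="source")


def _as_matrix(dist) -> np.ndarray:
    return dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)


def pop_pairwise_sums(hap_idx: np.ndarray, pop_codes: np.ndarray, d2: np.ndarray,
                      n_pops: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-population aggregates of squared distances.

    Returns ``(W, B)`` where ``W[p]`` is the within-population sum over
    unordered pairs and ``B[p, q]`` (p != q) the full between-population
    sum; ``B[p, p] = 2 W[p]``.  These aggregates make group-level sums
    of squares cheap, which the SAMOVA annealer exploits.
    """
    k = d2.shape[0]
    counts = np.zeros((n_pops, k))
    np.add.at(counts, (pop_codes, hap_idx), 1.0)
    B = counts @ d2 @ counts.T
    W = np.diag(B) / 2.0
    return W, B


def _components(W: np.ndarray, B: np.ndarray, n_k: np.ndarray,
                group_of: np.ndarray | None):
    """Variance components from population-level aggregates.

    ``group_of[p]`` is the group index of population p, or None for the
    one-level (populations only) design.  Returns a dict with df, SS,
    variance components and Phi statistics.
    """
    P = len(n_k)
    N = float(n_k.sum())
    ss_total = (W.sum() + (B.sum() - np.trace(B)) / 2.0) / N
    ss_wp = float(np.sum(W / n_k))

    if group_of is None:
        df_ap, df_wp = P - 1, int(N) - P
        ss_ap = ss_total - ss_wp
        vc = ss_wp / df_wp if df_wp > 0 else float("nan")
        n_c = (N - np.sum(n_k**2) / N) / (P - 1)
        va = (ss_ap / df_ap - vc) / n_c
        total = va + vc
        fst = va / total if total > 0 else float("nan")
        return {
            "df": {"Among populations": df_ap, "Within populations": df_wp},
            "ss": {"Among populations": ss_ap, "Within populations": ss_wp},
            "var": {"Among populations": va, "Within populations": vc},
            "phi": {"FST": fst},
        }

    G = int(group_of.max()) + 1
    if G < 2:
        raise AnalysisError("grouped AMOVA needs at least 2 groups")
    N_g = np.zeros(G)
    ss_groups = 0.0
    sum_np2_over_Ng = 0.0
    for g in range(G):
        members = np.where(group_of == g)[0]
        if members.size == 0:
            raise AnalysisError("empty group in partition")
        N_g[g] = n_k[members].sum()
        Bg = B[np.ix_(members, members)]
        pair_sum = (Bg.sum() - np.trace(Bg)) / 2.0 + W[members].sum()
        ss_groups += pair_sum / N_g[g]
        sum_np2_over_Ng += np.sum(n_k[members] ** 2) / N_g[g]

    df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
    ss_ag = ss_total - ss_groups
    ss_ap = ss_groups - ss_wp

    vc = ss_wp / df_wp if df_wp > 0 else float("nan")
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else float("nan")
    n2 = (sum_np2_over_Ng - np.sum(n_k**2) / N) / df_ag
    n3 = (N - np.sum(N_g**2) / N) / df_ag
    vb = (ss_ap / df_ap - vc) / n1 if df_ap > 0 else 0.0
    va = (ss_ag / df_ag - vc - n2 * vb) / n3
    total = va + vb + vc
    phi = {
        "FCT": va / total if total > 0 else float("nan"),
        "FSC": vb / (vb + vc) if (vb + vc) > 0 else float("nan"),
        "FST": (va + vb) / total if total > 0 else float("nan"),
    }
    return {
        "df": {
            "Among groups": df_ag,
            "Among populations within groups": df_ap,
            "Within populations": df_wp,
        },
        "ss": {
            "Among groups": ss_ag,
            "Among populations within groups": ss_ap,
            "Within populations": ss_wp,
        },
        "var": {
            "Among groups": va,
            "Among populations within groups": vb,
            "Within populations": vc,
        },
        "phi": phi,
    }


def _normalise_inputs(hap_idx, pops, dist):
    hap_idx = np.asarray(hap_idx, dtype=int)
    pops = np.asarray(pops)
    if hap_idx.shape != pops.shape:
        raise InputError("haplotype and population vectors differ in length")
    d2 = _as_matrix(dist)
    pop_names, pop_codes = np.unique(pops, return_inverse=True)
    return hap_idx, pop_names, pop_codes, d2


def amova(
    hap_idx,
    pops,
    dist,
    groups: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA from per-individual haplotype indices and population labels.

    ``hap_idx`` indexes rows of ``dist`` (squared inter-haplotype
    distances; for substitution counts the count itself plays the role
    of delta^2).  ``groups`` maps population label -> group label for
    the three-level design.  ``n_perm=0`` skips permutation testing.
    """
    hap_idx, pop_names, pop_codes, d2 = _normalise_inputs(hap_idx, pops, dist)
    P = len(pop_names)
    if P < 2:
        raise AnalysisError("AMOVA needs at least 2 populations")
    n_k = np.bincount(pop_codes, minlength=P).astype(float)
    W, B = pop_pairwise_sums(hap_idx, pop_codes, d2, P)

    group_of = None
    if groups is not None:
        missing = [p for p in pop_names if p not in groups]
        if missing:
            raise InputError(f"populations missing from group map: {missing}")
        group_names = sorted(set(groups[p] for p in pop_names))
        gcode = {g: i for i, g in enumerate(group_names)}
        group_of = np.array([gcode[groups[p]] for p in pop_names])

    comp = _components(W, B, n_k, group_of)
    flags = []
    total_var = sum(comp["var"].values())
    if not total_var > 0:
        flags.append("zero total variance: Phi statistics undefined")
    if group_of is not None:
        sizes = np.bincount(group_of)
        if np.any(sizes == 1):
            flags.append("singleton group(s): FSC based on remaining groups only")

    rows = {}
    for level in comp["df"]:
        var = comp["var"][level]
        rows[level] = {
            "df": comp["df"][level],
            "SS": comp["ss"][level],
            "variance": var,
            "pct": 100.0 * var / total_var if total_var > 0 else float("nan"),
        }
    rows["Total"] = {
        "df": sum(comp["df"].values()),
        "SS": sum(comp["ss"].values()),
        "variance": total_var,
        "pct": 100.0 if total_var > 0 else float("nan"),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")

    p_values: dict[str, float] = {}
    if n_perm > 0 and total_var > 0:
        rng = np.random.default_rng(seed)
        p_values = _permutation_pvalues(
            hap_idx, pop_codes, d2, n_k, group_of, comp["phi"], n_perm, rng
        )
    return AmovaResult(
        table=table, phi=comp["phi"], p_values=p_values,
        n_perm=n_perm if n_perm > 0 else None, seed=seed, flags=tuple(flags),
    )


def _permutation_pvalues(hap_idx, pop_codes, d2, n_k, group_of, phi_obs, n_perm, rng):
    P = len(n_k)
    N = len(hap_idx)
    counts = {stat: 0 for stat in phi_obs}

    def phis(codes, grouping):
        W, B = pop_pairwise_sums(hap_idx, codes, d2, P)
        return _components(W, B, n_k, grouping)["phi"]

    if group_of is None:
        for _ in range(n_perm):
            perm_codes = pop_codes[rng.permutation(N)]
            val = phis(perm_codes, None)["FST"]
            if val >= phi_obs["FST"] - 1e-12:
                counts["FST"] += 1
    else:
        group_of_ind = group_of[pop_codes]
        for _ in range(n_perm):
            # FST: individuals among populations (everything reshuffled)
            val = phis(pop_codes[rng.permutation(N)], group_of)["FST"]
            if val >= phi_obs["FST"] - 1e-12:
                counts["FST"] += 1
            # FSC: individuals among populations within their group
            perm_codes = pop_codes.copy()
            for g in np.unique(group_of):
                members = np.where(group_of_ind == g)[0]
                perm_codes[members] = perm_codes[members[rng.permutation(members.size)]]
            val = phis(perm_codes, group_of)["FSC"]
            if val >= phi_obs["FSC"] - 1e-12:
                counts["FSC"] += 1
            # FCT: whole populations among groups
            val = phis(pop_codes, group_of[rng.permutation(P)])["FCT"]
            if val >= phi_obs["FCT"] - 1e-12:
                counts["FCT"] += 1
    return {
        stat: (1 + c) / (n_perm + 1)
        for stat, c in counts.items()
        if not np.isnan(phi_obs[stat])
    }
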