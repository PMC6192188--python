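"""Independent oracle implementations used only by the test suite.

Each oracle deliberately takes the most literal route available (explicit
double loops, exact rational arithmetic, exhaustive enumeration) so that
agreement with the package is a genuine cross-check, not a tautology.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def brute_force_partition(seqs):
    """Haplotype partition by all-pairs string comparison."""
    groups = []
    for i, s in enumerate(seqs):
        for g in groups:
            if seqs[g[0]] == s:
                g.append(i)
                break
        else:
            groups.append([i])
    return [frozenset(g) for g in groups]


def brute_force_pi(seq_haps, d, L):
    """Unbiased nucleotide diversity as the mean over all individual pairs."""
    n = len(seq_haps)
    pairs = list(combinations(range(n), 2))
    total = sum(d[seq_haps[a]][seq_haps[b]] for a, b in pairs)
    return total / len(pairs) / L


def amova_oracle(hap_idx, pop_labels, d2, groups=None):
    """AMOVA variance components in exact rational arithmetic.

    Literal evaluation of the nested moments equations from explicit
    pairwise sums; ``d2`` must hold integers (or Fractions).
    Returns dict with variance components and Phi statistics as Fractions.
    """
    n = len(hap_idx)
    D = [[Fraction(int(d2[hap_idx[x]][hap_idx[y]])) for y in range(n)] for x in range(n)]
    pops = list(dict.fromkeys(pop_labels))
    members = {p: [i for i, l in enumerate(pop_labels) if l == p] for p in pops}
    n_k = {p: Fraction(len(members[p])) for p in pops}
    N = Fraction(n)
    P = len(pops)

    def ss(idxs):
        s = Fraction(0)
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                s += D[idxs[a]][idxs[b]]
        return s / len(idxs)

    ss_total = ss(list(range(n)))
    ss_wp = sum(ss(members[p]) for p in pops)

    if groups is None:
        df_ap, df_wp = P - 1, n - P
        ss_ap = ss_total - ss_wp
        vc = ss_wp / df_wp
        n_c = (N - sum(n_k[p] ** 2 for p in pops) / N) / (P - 1)
        va = (ss_ap / df_ap - vc) / n_c
        total = va + vc
        return {
            "Va": va, "Vc": vc,
            "FST": va / total if total != 0 else None,
            "SS": {"among": ss_ap, "within": ss_wp},
        }

    group_names = list(dict.fromkeys(groups[p] for p in pops))
    G = len(group_names)
    gmembers = {g: [p for p in pops if groups[p] == g] for g in group_names}
    N_g = {g: sum(n_k[p] for p in gmembers[g]) for g in group_names}
    ss_groups = Fraction(0)
    sum_np2_over_Ng = Fraction(0)
    for g in group_names:
        idxs = [i for p in gmembers[g] for i in members[p]]
        ss_groups += ss(idxs)
        sum_np2_over_Ng += sum(n_k[p] ** 2 for p in gmembers[g]) / N_g[g]

    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    ss_ag = ss_total - ss_groups
    ss_ap = ss_groups - ss_wp
    vc = ss_wp / df_wp
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else None
    n2 = (sum_np2_over_Ng - sum(n_k[p] ** 2 for p in pops) / N) / df_ag
    n3 = (N - sum(N_g[g] ** 2 for g in group_names) / N) / df_ag
    vb = (ss_ap / df_ap - vc) / n1 if df_ap > 0 else Fraction(0)
    va = (ss_ag / df_ag - vc - n2 * vb) / n3
    total = va + vb + vc
    return {
        "Va": va, "Vb": vb, "Vc": vc,
        "FCT": va / total if total != 0 else None,
        "FSC": vb / (vb + vc) if (vb + vc) != 0 else None,
        "FST": (va + vb) / total if total != 0 else None,
    }


def exhaustive_fct(counts, d2, k):
    """Best Phi_CT over every partition of the populations into k
    non-empty groups, by exhaustive enumeration."""
    from hapgeo.amova import _components

    counts = np.asarray(counts, dtype=float)
    P = counts.shape[0]
    n_k = counts.sum(axis=1)
    B = counts @ np.asarray(d2, dtype=float) @ counts.T
    W = np.diag(B) / 2.0

    def partitions(items, k):
        if k == 1:
            yield [items]
            return
        if len(items) == k:
            yield [[i] for i in items]
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest, k):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
        for part in partitions(rest, k - 1):
            yield [[head]] + part

    best = -np.inf
    best_part = None
    for part in partitions(list(range(P)), k):
        group_of = np.empty(P, dtype=int)
        for g, grp in enumerate(part):
            group_of[grp] = g
        fct = _components(W, B, n_k, group_of)["phi"]["FCT"]
        if not np.isnan(fct) and fct > best:
            best, best_part = fct, part
    return best, best_part


def exhaustive_mst_weight(d):
    """Minimum spanning tree weight by enumerating all spanning trees."""
    import networkx as nx

    k = d.shape[0]
    edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    best = np.inf
    for subset in combinations(edges, k - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == k and nx.is_connected(g):
            w = sum(d[i, j] for i, j in subset)
            best = min(best, w)
    return best


def tajima_d_textbook(n, S, khat):
    """Tajima's D from the published coefficient recipe, written out plainly."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (khat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def stirling_unsigned(n):
    """Exact unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    return row


def fus_fs_exact(n, k0, theta):
    """Fu's Fs via exact rational Ewens probabilities (theta rational)."""
    theta = Fraction(theta)
    s = stirling_unsigned(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    probs = [Fraction(s[k]) * theta**k / rising for k in range(n + 1)]
    sp = sum(probs[k0:])
    return float(np.log(float(sp) / float(1 - sp)))


def raggedness_oracle(hist):
    """Harpending's raggedness by an explicit index-by-index loop."""
    f = list(np.asarray(hist, dtype=float) / np.sum(hist))
    f = [0.0] + f + [0.0]
    return sum((f[i] - f[i - 1]) ** 2 for i in range(1, len(f)))
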