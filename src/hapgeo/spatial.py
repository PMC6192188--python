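"""Geographic distances, isolation by distance (Mantel test) and
population-pairwise genetic distances."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "geographic_distance_matrix",
    "pairwise_phist",
    "MantelResult",
    "mantel_test",
]


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (Earth radius 6371.0 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(coords: dict[str, tuple[float, float]],
                               order: list[str] | None = None) -> pd.DataFrame:
    """Symmetric population-pairwise great-circle distance matrix (km)."""
    pops = order if order is not None else list(coords)
    missing = [p for p in pops if p not in coords]
    if missing:
        raise InputError(f"populations without coordinates: {missing}")
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_km(*coords[pops[i]], *coords[pops[j]])
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=pops, columns=pops)


def pairwise_phist(table_counts, dist, linearized: bool = True) -> pd.DataFrame:
    """Population-pairwise Phi_ST from two-population AMOVAs.

    With ``linearized`` (default) returns Phi_ST / (1 - Phi_ST), the
    Slatkin transform commonly used for isolation-by-distance; pairs
    with Phi_ST = 1 get +inf.  Undefined pairs (zero variance) get 0.
    """
    from .amova import _components  # local import avoids cycle

    counts = np.asarray(table_counts, dtype=float)
    pops = list(table_counts.index)
    d2 = np.asarray(dist.matrix if hasattr(dist, "matrix") else dist, dtype=float)
    P = len(pops)
    out = np.zeros((P, P))
    B = counts @ d2 @ counts.T
    W = np.diag(B) / 2.0
    for i in range(P):
        for j in range(i + 1, P):
            idx = [i, j]
            Wij = W[idx]
            Bij = B[np.ix_(idx, idx)]
            n_ij = counts[idx].sum(axis=1)
            comp = _components(Wij, Bij, n_ij, None)
            phi = comp["phi"]["FST"]
            if math.isnan(phi):
                val = 0.0
            elif linearized:
                val = phi / (1.0 - phi) if phi < 1.0 else float("inf")
            else:
                val = phi
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=pops, columns=pops)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None = None
    alternative: str = "greater"


def mantel_test(genetic, geographic, n_perm: int = 1000, seed: int | None = None,
                alternative: str = "greater") -> MantelResult:
    """Mantel correlation between two population-pairwise matrices.

    r is the Pearson correlation of the off-diagonal upper triangles;
    the null distribution permutes rows/columns of one matrix
    simultaneously.  One-sided p for r > 0 by default ("greater");
    "two-sided" compares |r|.  The +1 p-value convention is used.
    """
    g = np.asarray(genetic, dtype=float)
    e = np.asarray(geographic, dtype=float)
    if g.shape != e.shape or g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise InputError("matrices must be square and of equal shape")
    n = g.shape[0]
    if n < 4:
        raise AnalysisError("Mantel test needs at least 4 populations")
    if isinstance(genetic, pd.DataFrame) and isinstance(geographic, pd.DataFrame):
        if list(genetic.index) != list(geographic.index):
            raise InputError("matrices must share the same population order")
    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        x, y = mat[iu], e[iu]
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(g)
    if math.isnan(r_obs):
        return MantelResult(float("nan"), float("nan"), n_perm, seed, alternative)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(g[np.ix_(perm, perm)])
        if math.isnan(r_p):
            continue
        if alternative == "greater":
            if r_p >= r_obs - 1e-12:
                count += 1
        else:
            if abs(r_p) >= abs(r_obs) - 1e-12:
                count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, seed, alternative)
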