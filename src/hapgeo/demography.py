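"""Demographic inference from pairwise sequence differences.

Mismatch distribution
    The histogram of pairwise nucleotide differences over all
    N(N-1)/2 sequence pairs.  Under a sudden (stepwise) demographic
    expansion the expected class probabilities follow the
    Rogers-Harpending model: a population at mutation-drift equilibrium
    with theta0 = 2*N0*u grows instantaneously to theta1 = 2*N1*u at
    mutational time tau = 2*u*t before the present.  Writing
    Fhat_j(theta) = theta^j / (1+theta)^(j+1) for the equilibrium
    (geometric) distribution, the probability of j differences is

        F_j(tau, theta0, theta1) = Fhat_j(theta1)
            + exp(-tau (theta1+1)/theta1)
              * sum_{i=0}^{j} tau^i/i! * [Fhat_{j-i}(theta0) - Fhat_{j-i}(theta1)]

    which is the pair-coalescence integral: pairs coalescing since the
    expansion contribute the theta1 equilibrium term, pairs surviving
    into the ancestral epoch carry Poisson(tau) extra differences on top
    of the theta0 equilibrium.

Goodness of fit uses the sum of squared deviations (SSD) between the
observed and fitted histograms and Harpending's raggedness index, with
p-values from a parametric bootstrap (coalescent simulation under the
fitted model, refitting each replicate).

Neutrality tests: Tajima's D (with the beta-distribution p-value
approximation) and Fu's Fs computed exactly from the Ewens sampling
distribution via log-space Stirling numbers of the first kind.

Expansion dating: t = tau / (2u) generations with u = mu * k * g the
per-generation mutation rate of the whole locus (mu substitution rate
per site per year, k aligned length in bp, g generation time in years).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import AnalysisError, InputError
from .haplotypes import DistanceMatrix

__all__ = [
    "mismatch_histogram",
    "mismatch_from_counts",
    "sudden_expansion_pmf",
    "MismatchFit",
    "fit_sudden_expansion",
    "raggedness",
    "MismatchResult",
    "bootstrap_gof",
    "tajimas_d",
    "ewens_log_pmf",
    "fus_fs",
    "fus_fs_pvalue",
    "ExpansionEstimate",
    "expansion_time",
    "strict_clock_divergence",
    "net_divergence_per_site",
]


# --- observed histogram -----------------------------------------------------

def _as_matrix(dist) -> np.ndarray:
    return dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)


def mismatch_from_counts(counts, dist) -> np.ndarray:
    """Relative mismatch frequencies from haplotype counts + distances.

    Exact pair counting: c_i*c_j pairs at distance d_ij (i < j) and
    C(c_i, 2) pairs at distance 0.
    """
    c = np.asarray(np.ravel(counts), dtype=float)
    d = _as_matrix(dist)
    n = c.sum()
    if n < 2:
        raise AnalysisError("mismatch distribution needs at least 2 individuals")
    max_d = int(d.max())
    freq = np.zeros(max_d + 1)
    freq[0] += float(np.sum(c * (c - 1) / 2.0))
    k = len(c)
    for i in range(k):
        for j in range(i + 1, k):
            freq[int(d[i, j])] += c[i] * c[j]
    return freq / freq.sum()


def mismatch_histogram(hap_idx, dist) -> np.ndarray:
    """Relative mismatch frequencies from per-individual haplotype indices."""
    hap_idx = np.asarray(hap_idx, dtype=int)
    d = _as_matrix(dist)
    counts = np.bincount(hap_idx, minlength=d.shape[0])
    return mismatch_from_counts(counts, d)


# --- sudden-expansion model -------------------------------------------------

def _equilibrium_pmf(n_classes: int, theta: float) -> np.ndarray:
    j = np.arange(n_classes)
    if theta <= 0:
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def sudden_expansion_pmf(n_classes: int, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Rogers-Harpending expected mismatch probabilities for classes 0..n_classes-1."""
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise InputError("tau, theta0, theta1 must be non-negative")
    f1 = _equilibrium_pmf(n_classes, theta1)
    f0 = _equilibrium_pmf(n_classes, theta0)
    if theta1 <= 0:
        # no post-expansion coalescence on the mutational scale: pure Poisson shift
        decay = math.exp(-tau)
    else:
        decay = math.exp(-tau * (theta1 + 1.0) / theta1)
    diff = f0 - f1
    # convolution with the tau^i/i! kernel (its exp(-tau) folded into `decay`),
    # evaluated in log space to survive large tau
    i = np.arange(n_classes)
    if tau > 0:
        kernel = np.exp(i * math.log(tau) - special.gammaln(i + 1.0))
    else:
        kernel = np.zeros(n_classes)
        kernel[0] = 1.0
    conv = np.convolve(kernel, diff)[:n_classes]
    return f1 + decay * conv


@dataclass
class MismatchFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    flags: tuple[str, ...] = ()

    def expected(self, n_classes: int) -> np.ndarray:
        return sudden_expansion_pmf(n_classes, self.tau, self.theta0, self.theta1)


# theta values at or above this cap are operationally "infinite": the
# post-expansion coalescence term is negligible and SSD is flat in theta1
_THETA_CAP = 1e4


def _ssd(params, hist: np.ndarray, tau_max: float) -> float:
    tau, th0, th1 = params
    if not (0 <= tau <= tau_max and 0 <= th0 <= _THETA_CAP and 0 <= th1 <= _THETA_CAP):
        return np.inf
    exp = sudden_expansion_pmf(len(hist), tau, th0, th1)
    return float(np.sum((hist - exp) ** 2))


def fit_sudden_expansion(hist, theta1_infinite: bool = False) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to a mismatch histogram.

    A coarse grid over (tau, theta0, theta1) is refined by Nelder-Mead;
    SSD is summed over the observed classes 0..max.  With
    ``theta1_infinite`` the classical two-parameter model (post-expansion
    population effectively infinite) is fitted by profiling theta1 at a
    large value.  Bounds: tau in [0, 2*max_class], theta0, theta1 >= 0.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or len(hist) < 1:
        raise InputError("histogram must be a 1-D frequency vector")
    hist = hist / hist.sum()
    if len(hist) < 2 or hist[0] >= 1.0 - 1e-12:
        return MismatchFit(0.0, 0.0, 0.0, 0.0, flags=("degenerate single-class histogram",))
    max_class = len(hist) - 1
    tau_max = 2.0 * max_class
    mean_d = float(np.dot(np.arange(len(hist)), hist))

    taus = np.linspace(0.0, tau_max, 25)
    th0s = np.unique(np.concatenate([[0.0], np.geomspace(0.01, max(mean_d, 0.1) * 2, 8)]))
    th1s = [_THETA_CAP] if theta1_infinite else np.geomspace(0.1, _THETA_CAP, 10)
    best = None
    for tau in taus:
        for th0 in th0s:
            for th1 in th1s:
                val = _ssd((tau, th0, th1), hist, tau_max)
                if best is None or val < best[1]:
                    best = ((tau, th0, th1), val)
    x0 = np.array(best[0])

    if theta1_infinite:
        def obj(x):
            return _ssd((x[0], x[1], _THETA_CAP), hist, tau_max)
        res = optimize.minimize(obj, x0[:2], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        tau, th0 = np.clip(res.x, 0.0, [tau_max, _THETA_CAP])
        return MismatchFit(float(tau), float(th0), math.inf,
                           _ssd((tau, th0, _THETA_CAP), hist, tau_max),
                           flags=("theta1 profiled at infinity",))

    res = optimize.minimize(lambda x: _ssd(x, hist, tau_max), x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    tau, th0, th1 = np.clip(res.x, 0.0, [tau_max, _THETA_CAP, _THETA_CAP])
    ssd = _ssd((tau, th0, th1), hist, tau_max)
    flags = ()
    if th1 < th0:
        flags = ("theta1 < theta0: fitted model implies contraction",)
    return MismatchFit(float(tau), float(th0), float(th1), ssd, flags=flags)


def raggedness(hist) -> float:
    """Harpending's raggedness index.

    r = sum_{i=0}^{d+1} (F_i - F_{i-1})^2 with the boundary convention
    F_{-1} = F_{d+1} = 0, i.e. both the leading rise into class 0 and
    the trailing fall after the last class count as steps.
    """
    hist = np.asarray(hist, dtype=float)
    padded = np.concatenate([[0.0], hist / hist.sum(), [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


@dataclass
class MismatchResult:
    histogram: np.ndarray
    fit: MismatchFit
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None
    n_boot: int | None = None
    seed: int | None = None


def bootstrap_gof(hist, fit: MismatchFit, n_individuals: int, n_boot: int = 1000,
                  seed: int | None = None) -> MismatchResult:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Simulates ``n_boot`` coalescent samples of ``n_individuals`` under
    the fitted sudden-expansion model, refits each, and reports
    p = (1 + #{replicate statistic >= observed}) / (B + 1).
    """
    from .simulate import simulate_mismatch_counts  # deferred: avoids import cycle

    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    hist = np.asarray(hist, dtype=float)
    hist = hist / hist.sum()
    obs_ssd = fit.ssd
    obs_rag = raggedness(hist)
    rng = np.random.default_rng(seed)
    theta1 = min(fit.theta1, _THETA_CAP) if math.isfinite(fit.theta1) else _THETA_CAP
    n_ssd = n_rag = 0
    for _ in range(n_boot):
        diffs = simulate_mismatch_counts(n_individuals, fit.tau, fit.theta0, theta1, rng)
        sim_hist = np.bincount(diffs)
        sim_hist = sim_hist / sim_hist.sum()
        sim_fit = fit_sudden_expansion(sim_hist)
        if sim_fit.ssd >= obs_ssd - 1e-15:
            n_ssd += 1
        if raggedness(sim_hist) >= obs_rag - 1e-15:
            n_rag += 1
    return MismatchResult(
        histogram=hist, fit=fit, raggedness=obs_rag,
        p_ssd=(1 + n_ssd) / (n_boot + 1), p_raggedness=(1 + n_rag) / (n_boot + 1),
        n_boot=n_boot, seed=seed,
    )


# --- neutrality tests -------------------------------------------------------

def tajimas_d(n: int, S: int, k_hat: float) -> tuple[float, float]:
    """Tajima's D with the beta-distribution p-value approximation.

    n sequences, S segregating sites, k_hat mean pairwise differences.
    """
    if n < 4:
        raise AnalysisError("Tajima's D needs n >= 4")
    if S < 1:
        raise AnalysisError("Tajima's D undefined for S = 0")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    d = (k_hat - S / a1) / math.sqrt(var)

    # beta approximation on the large-S range of D (Tajima 1989)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / a1) / math.sqrt(e2)
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    u = (d - dmin) / (dmax - dmin)
    u = min(max(u, 0.0), 1.0)
    cdf = stats.beta.cdf(u, beta, alpha)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return d, min(p, 1.0)


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, 1st kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        new[1:m + 1] = row[0:m]
        with np.errstate(divide="ignore"):
            grown = row + math.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new = np.logaddexp(new, grown)
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if n < 1 or theta <= 0:
        raise InputError("Ewens distribution needs n >= 1, theta > 0")
    ls = _log_stirling_row(n)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    k = np.arange(n + 1)
    with np.errstate(invalid="ignore"):
        return ls + k * math.log(theta) - log_rising


def fus_fs(n: int, k0: int, theta_pi: float) -> float:
    """Fu's Fs statistic.

    S' = P(K >= k0 | theta_pi, n) under the Ewens sampling formula,
    Fs = ln(S' / (1 - S')).  Returns -inf / +inf (with a warning) when
    S' underflows to 0 or rounds to 1.
    """
    if n < 2 or k0 < 1:
        raise AnalysisError("Fu's Fs needs n >= 2 and k0 >= 1")
    if theta_pi <= 0:
        warnings.warn("theta_pi <= 0: S' -> 0, Fs -> -inf")
        return -math.inf if k0 > 1 else math.inf
    logpmf = ewens_log_pmf(n, theta_pi)
    log_sp = special.logsumexp(logpmf[k0:])
    if log_sp >= 0.0:  # numerically all mass at K >= k0
        warnings.warn("S' rounds to 1: Fs -> +inf")
        return math.inf
    sp = math.exp(log_sp)
    if sp == 0.0:
        warnings.warn("S' underflows to 0: Fs -> -inf")
        return -math.inf
    log_one_minus = special.logsumexp(logpmf[:k0])
    return float(log_sp - log_one_minus)


def fus_fs_pvalue(n: int, k0: int, theta_pi: float, n_sim: int = 1000,
                  seed: int | None = None) -> tuple[float, float]:
    """Simulation p-value for Fu's Fs under neutrality.

    Simulates constant-size coalescent samples at theta_pi, recomputes
    Fs from each replicate's own (k_hat, K), and reports
    p = (1 + #{Fs_sim <= Fs_obs}) / (B + 1) (small/negative Fs indicates
    an allele excess, the expansion signal).
    """
    from .simulate import simulate_sample_stats  # deferred: avoids import cycle

    if n_sim < 1:
        raise InputError("n_sim must be >= 1")
    fs_obs = fus_fs(n, k0, theta_pi)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        k_hat_b, k0_b, _ = simulate_sample_stats(n, theta_pi, rng)
        fs_b = fus_fs(n, k0_b, k_hat_b) if k_hat_b > 0 else math.inf
        if fs_b <= fs_obs + 1e-12:
            count += 1
    return fs_obs, (1 + count) / (n_sim + 1)


# --- expansion dating -------------------------------------------------------

@dataclass
class ExpansionEstimate:
    tau: float
    mu: float                   # substitution rate, per site per year
    k: float                    # aligned length, bp
    g: float                    # generation time, years
    u: float = field(init=False)
    t_generations: float = field(init=False)
    t_years: float = field(init=False)

    def __post_init__(self) -> None:
        self.u = self.mu * self.k * self.g
        self.t_generations = self.tau / (2.0 * self.u)
        self.t_years = self.t_generations * self.g


def expansion_time(tau: float, mu: float, k: float, g: float) -> ExpansionEstimate:
    """Expansion time t = tau / (2u), u = mu*k*g mutations per generation.

    Reported both in generations (the natural unit of the formula) and
    in years (generations * g).
    """
    if mu <= 0 or k <= 0 or g <= 0:
        raise InputError("mu, k and g must be positive")
    if tau < 0:
        raise InputError("tau must be non-negative")
    return ExpansionEstimate(tau, mu, k, g)


def net_divergence_per_site(counts_a, counts_b, dist, L: float) -> float:
    """Net between-group distance d_net = d_AB - (d_A + d_B)/2, per site."""
    ca = np.asarray(np.ravel(counts_a), dtype=float)
    cb = np.asarray(np.ravel(counts_b), dtype=float)
    d = _as_matrix(dist)
    pa, pb = ca / ca.sum(), cb / cb.sum()
    d_between = float(pa @ d @ pb)
    d_within_a = float(pa @ d @ pa)
    d_within_b = float(pb @ d @ pb)
    return (d_between - (d_within_a + d_within_b) / 2.0) / L


def strict_clock_divergence(net_distance_per_site: float, mu: float) -> float:
    """Strict-clock divergence time T = d_net / (2 mu) in years.

    Negative net distances (possible after the within-group correction)
    are clamped to zero with a warning.
    """
    if mu <= 0:
        raise InputError("mu must be positive")
    if net_distance_per_site < 0:
        warnings.warn("negative net distance clamped to 0")
        net_distance_per_site = 0.0
    return net_distance_per_site / (2.0 * mu)
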