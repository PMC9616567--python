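"""Selection inference: gamma DFE fitting and the asymptotic rate of adaptive evolution.

The model is the equilibrium Poisson random field.  A new deleterious
mutation with scaled selection coefficient S = 2*N_e*s (S >= 0 measures the
strength of purifying selection) contributes to the sample spectrum through
the stationary sojourn density

    tau(q; S) = (exp(-2Sq) - exp(-2S)) / ((1 - exp(-2S)) * q * (1 - q)),

which reduces to the neutral 1/q as S -> 0.  Integrating the binomial
sampling kernel over tau and over a gamma distribution of S gives the
expected unfolded spectrum; its neutral limit reproduces the Watterson
expectations theta*L/i.  The DFE (gamma shape and mean of 2*N_e*s) is fit by
Poisson maximum likelihood to the nonsynonymous spectrum with the mutation
rate pinned to a multiple (default 2.76, the 0-fold/4-fold mutation-rate
ratio) of the synonymous Watterson theta, so that variants removed by strong
selection are accounted for rather than absorbed into theta.

The rate of adaptive evolution is summarised per frequency bin as
alpha(x) = 1 - (pN(x)/pS(x)) / (dN/dS) and extrapolated to x = 1 with the
asymptotic form alpha(x) = a + b*exp(-c*x), fit by a brute-force grid search
refined with nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .sfs import SFSPair, bootstrap_sfs, fold_counts, watterson_theta

DFE_BIN_NAMES = ("nearly_neutral", "intermediate", "deleterious")
S_MAX_DEFAULT = 5000.0
N_S_NODES_DEFAULT = 200


def _binom_kernel(n: int, n_q: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes on (0,1) and C(n,i) q^i (1-q)^(n-i) for i=1..n-1."""
    nodes, weights = np.polynomial.legendre.leggauss(n_q)
    q = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    i = np.arange(1, n)[:, None]
    logpmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(q)[None, :]
        + (n - i) * np.log1p(-q)[None, :]
    )
    return q, w, np.exp(logpmf)


def expected_sfs_gamma(
    n: int,
    theta_n: float,
    shape: float,
    mean_2nes: float,
    L: float = 1.0,
    *,
    s_max: float = S_MAX_DEFAULT,
    n_s_nodes: int = N_S_NODES_DEFAULT,
    n_q: int = 400,
    distortion: np.ndarray | None = None,
) -> np.ndarray:
    """Expected unfolded SFS counts under an equilibrium PRF with gamma DFE.

    Parameters
    ----------
    n : sample size in haplotypes.
    theta_n : population mutation rate per site at the (nonsynonymous) class.
    shape, mean_2nes : gamma parameters of the DFE over S = 2*N_e*s.
    L : number of sites; expectations scale linearly.
    s_max : integration cap for S; gamma mass above it is evaluated at s_max.
    n_s_nodes : number of log-spaced S cells for the gamma mixture.
    n_q : Gauss-Legendre nodes for the frequency integral.
    distortion : optional per-bin multipliers (length n-1) standing in for
        demographic distortion of the neutral spectrum shape.

    Returns
    -------
    numpy.ndarray of length n-1 with E[xi_i], scaled so that the neutral
    limit (mean_2nes -> 0) equals theta_n * L / i.
    """
    if n < 4:
        raise ValueError("sample size n must be >= 4")
    if shape <= 0 or mean_2nes <= 0:
        raise ValueError("gamma shape and mean must be positive")
    q, w, pmf = _binom_kernel(n, n_q)
    # H(S)_i = integral tau*binom dq; tau*q*(1-q) has the bounded form below
    edges = np.geomspace(1e-8, s_max, n_s_nodes + 1)
    nodes = np.sqrt(edges[:-1] * edges[1:])
    gamma_dist = stats.gamma(shape, scale=mean_2nes / shape)
    cdf = gamma_dist.cdf(edges)
    cell_mass = np.diff(cdf)
    mass_below = cdf[0]
    mass_above = 1.0 - cdf[-1]

    two_s = 2.0 * nodes
    # bounded sojourn factor f(q;S) = tau * q(1-q) = (e^{-2Sq}-e^{-2S})/(1-e^{-2S})
    expo = np.exp(-np.minimum(two_s[:, None] * q[None, :], 745.0))
    tail = np.exp(-np.minimum(two_s, 745.0))
    f = (expo - tail[:, None]) / (1.0 - tail[:, None])
    integrand_weights = w[None, :] / (q * (1.0 - q))[None, :]
    # H has shape (n_s_nodes, n-1)
    H = (f * integrand_weights) @ pmf.T

    neutral = 1.0 / np.arange(1, n)
    h_smax = H[-1]
    mixed = cell_mass @ H + mass_below * neutral + mass_above * h_smax
    out = theta_n * L * mixed
    if distortion is not None:
        out = out * np.asarray(distortion, dtype=float)
    return out


def mean_fixation_factor(shape: float, mean_2nes: float, *, s_max: float = S_MAX_DEFAULT,
                         n_s_nodes: int = N_S_NODES_DEFAULT) -> float:
    """E over the gamma DFE of the relative fixation probability 2S/(e^{2S}-1).

    This is the expected nonsynonymous/neutral substitution-rate ratio for
    nonadaptive mutations under the equilibrium model (1 in the neutral limit).
    """
    if shape <= 0 or mean_2nes <= 0:
        raise ValueError("gamma shape and mean must be positive")
    edges = np.geomspace(1e-8, s_max, n_s_nodes + 1)
    nodes = np.sqrt(edges[:-1] * edges[1:])
    gamma_dist = stats.gamma(shape, scale=mean_2nes / shape)
    cdf = gamma_dist.cdf(edges)
    cell_mass = np.diff(cdf)
    two_s = 2.0 * nodes
    v = np.where(two_s > 700, 0.0, two_s / np.expm1(np.minimum(two_s, 700)))
    return float(cell_mass @ v + cdf[0] * 1.0 + (1.0 - cdf[-1]) * 0.0)


def dfe_bin_proportions(shape: float, mean_2nes: float) -> np.ndarray:
    """Discretize the gamma DFE into nearly neutral (2Ns<1), intermediate
    (1<=2Ns<=10) and deleterious (2Ns>10) mass."""
    g = stats.gamma(shape, scale=mean_2nes / shape)
    c1, c10 = g.cdf(1.0), g.cdf(10.0)
    return np.array([c1, c10 - c1, 1.0 - c10])


@dataclass
class DFEFit:
    """Maximum-likelihood gamma DFE conditional on the neutral mutation rate."""

    shape: float
    mean_2nes: float
    theta_s: float
    theta_n: float
    bins: np.ndarray
    loglik: float
    n: int
    folded: bool
    bootstrap_bins: np.ndarray | None = None
    bootstrap_params: np.ndarray | None = None


def _dfe_negloglik(params: np.ndarray, xi_obs: np.ndarray, n: int, folded: bool,
                   theta_n: float, L: float, n_q: int) -> float:
    shape, mean = np.exp(params)
    if not (1e-3 <= shape <= 50 and 1e-3 <= mean <= 1e7):
        return 1e12
    mu = expected_sfs_gamma(n, theta_n, shape, mean, L=L, n_q=n_q)
    if folded:
        mu = fold_counts(mu, n)
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(mu) - np.sum(xi_obs * np.log(mu)))


_DFE_STARTS = [(0.1, 50.0), (0.3, 400.0), (0.5, 2000.0), (1.0, 10.0), (2.0, 1000.0)]


def fit_dfe(
    sfs: SFSPair,
    theta_multiplier: float = 2.76,
    *,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
    n_q: int = 400,
    starts: list[tuple[float, float]] | None = None,
) -> DFEFit:
    """Fit the deleterious gamma DFE to the nonsynonymous spectrum.

    theta at synonymous sites comes from Watterson's estimator on the
    synonymous spectrum and is multiplied by ``theta_multiplier`` to give the
    nonsynonymous mutation rate, which is held fixed while (shape, mean) are
    optimized by Poisson maximum likelihood from several starting points.
    With ``n_bootstrap`` > 0 the fit is repeated on multinomial bootstrap
    replicates of the SFS, populating ``bootstrap_bins``.
    """
    if sfs.l_s <= 0 or sfs.l_n <= 0:
        raise ValueError("callable totals l_s and l_n must be positive")
    theta_s = watterson_theta(sfs.xi_s, sfs.n, sfs.l_s)
    theta_n = theta_multiplier * theta_s

    best = None
    for s0, m0 in starts or _DFE_STARTS:
        res = optimize.minimize(
            _dfe_negloglik,
            np.log([s0, m0]),
            args=(sfs.xi_n, sfs.n, sfs.folded, theta_n, sfs.l_n, n_q),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("DFE optimization failed from all starting points")
    shape, mean = np.exp(best.x)
    fit = DFEFit(
        shape=float(shape),
        mean_2nes=float(mean),
        theta_s=theta_s,
        theta_n=theta_n,
        bins=dfe_bin_proportions(shape, mean),
        loglik=-float(best.fun),
        n=sfs.n,
        folded=sfs.folded,
    )
    if n_bootstrap > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        reps = bootstrap_sfs(sfs, n_bootstrap, rng)
        bins = np.empty((n_bootstrap, 3))
        params = np.empty((n_bootstrap, 2))
        warm = [(fit.shape, fit.mean_2nes)] + _DFE_STARTS[:2]
        for r, rep in enumerate(reps):
            bfit = fit_dfe(rep, theta_multiplier, n_q=n_q, starts=warm)
            bins[r] = bfit.bins
            params[r] = (bfit.shape, bfit.mean_2nes)
        fit.bootstrap_bins = bins
        fit.bootstrap_params = params
    return fit


def dfe_bootstrap_p(fit_a: DFEFit, fit_b: DFEFit) -> np.ndarray:
    """Doubled-overlap bootstrap p-values per DFE bin.

    For each discretized bin, p = 2 * min(Pr*(diff <= 0), Pr*(diff >= 0))
    over paired bootstrap differences, capped at 1.  The smallest attainable
    value is 2/reps.
    """
    if fit_a.bootstrap_bins is None or fit_b.bootstrap_bins is None:
        raise ValueError("both fits need bootstrap replicates")
    a, b = fit_a.bootstrap_bins, fit_b.bootstrap_bins
    if a.shape != b.shape:
        raise ValueError("bootstrap replicate counts differ; cannot pair")
    if a.shape[0] < 100:
        raise ValueError("need >=100 bootstrap replicates")
    diff = a - b
    reps = diff.shape[0]
    # clamp at 1/reps so the smallest attainable p is 2/reps
    lo = np.maximum((diff <= 0).sum(axis=0), 1) / reps
    hi = np.maximum((diff >= 0).sum(axis=0), 1) / reps
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def alpha_of_x(sfs: SFSPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency-bin adaptive proportion alpha(x).

    alpha(x) = 1 - (pN(x)/pS(x)) / (dN/dS) on the unfolded spectrum; bins
    with pS(x) = 0 are masked.  Returns (x, alpha) for the unmasked bins.
    """
    if sfs.folded:
        raise ValueError("alpha(x) requires an unfolded SFS")
    if sfs.d_s <= 0 or sfs.d_n <= 0:
        raise ValueError("alpha(x) requires positive dN and dS")
    x = sfs.frequencies
    keep = sfs.xi_s > 0
    ratio = (sfs.xi_n[keep] / sfs.xi_s[keep]) / (sfs.d_n / sfs.d_s)
    return x[keep], 1.0 - ratio


@dataclass
class AlphaFit:
    """Asymptotic alpha(x) = a + b*exp(-c*x) fit."""

    a: float
    b: float
    c: float
    x: np.ndarray
    alpha_x: np.ndarray
    rss: float
    ci: tuple[float, float] | None = None
    bootstrap_alpha: np.ndarray | None = None

    @property
    def alpha_asymptotic(self) -> float:
        """The fitted curve evaluated at x = 1 (the reported alpha)."""
        return float(self.a + self.b * np.exp(-self.c))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.exp(-self.c * np.asarray(x, dtype=float))


GRID_A = np.linspace(-1.0, 1.0, 20)
GRID_B = np.linspace(-2.0, 2.0, 20)
GRID_C = np.linspace(0.1, 50.0, 20)


def _grid_seed(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Brute-force search of the (a, b, c) box for the best RSS grid point."""
    e = np.exp(-GRID_C[:, None] * x[None, :])  # (c, x)
    # residuals for all (a, b, c): y - a - b*e
    pred = GRID_B[None, :, None, None] * e[None, None, :, :]  # b, c broadcast
    pred = GRID_A[:, None, None, None] + pred
    rss = ((y[None, None, None, :] - pred) ** 2).sum(axis=-1)
    ia, ib, ic = np.unravel_index(np.argmin(rss), rss.shape)
    return float(GRID_A[ia]), float(GRID_B[ib]), float(GRID_C[ic])


def _nls(x: np.ndarray, y: np.ndarray, p0: tuple[float, float, float]) -> tuple[np.ndarray, float]:
    def resid(p):
        return p[0] + p[1] * np.exp(-p[2] * x) - y

    def jac(p):
        e = np.exp(-p[2] * x)
        return np.column_stack([np.ones_like(x), e, -p[1] * x * e])

    res = optimize.least_squares(
        resid, p0, jac=jac, bounds=([-10.0, -20.0, 1e-4], [1.0, 20.0, 200.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return res.x, float(np.sum(res.fun ** 2))


def fit_asymptotic_alpha(
    x: np.ndarray,
    alpha_x: np.ndarray,
    *,
    x_min: float | None = None,
    sfs: SFSPair | None = None,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
) -> AlphaFit:
    """Fit alpha(x) = a + b*exp(-c*x) by grid search + nonlinear least squares.

    A coarse brute-force scan of the (a, b, c) box seeds a bounded
    least-squares refinement.  ``x_min`` excludes low-frequency bins
    (x < x_min) from the fit -- the singleton class is dominated by weakly
    deleterious variants (and, in real data, sequencing error) and otherwise
    drags the extrapolation down.  When ``sfs`` is given and
    ``n_bootstrap`` > 0, the asymptote's 95% percentile CI is computed by
    refitting (same ``x_min``) on multinomial bootstrap replicates of the
    spectrum, divergence counts resampled too.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(alpha_x, dtype=float)
    if x_min is not None:
        keep = x >= x_min
        x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need >=4 unmasked frequency bins")
    p0 = _grid_seed(x, y)
    params, rss = _nls(x, y, p0)
    fit = AlphaFit(a=float(params[0]), b=float(params[1]), c=float(params[2]),
                   x=x, alpha_x=y, rss=rss)
    if n_bootstrap > 0:
        if sfs is None:
            raise ValueError("bootstrap CI needs the source SFS")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        reps = bootstrap_sfs(sfs, n_bootstrap, rng)
        boot = np.full(n_bootstrap, np.nan)
        for r, rep in enumerate(reps):
            if rep.d_s <= 0 or rep.d_n <= 0:
                continue
            bx, by = alpha_of_x(rep)
            if x_min is not None:
                bkeep = bx >= x_min
                bx, by = bx[bkeep], by[bkeep]
            if bx.size < 4:
                continue
            bp, _ = _nls(bx, by, tuple(params))
            boot[r] = bp[0] + bp[1] * np.exp(-bp[2])
        boot = boot[np.isfinite(boot)]
        if boot.size:
            fit.ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
            fit.bootstrap_alpha = boot
    return fit


def alpha_lrt(
    set_x: np.ndarray, set_alpha: np.ndarray,
    genome_x: np.ndarray, genome_alpha: np.ndarray,
) -> tuple[float, float]:
    """Gaussian-error LRT: shared (a,b,c) on pooled bins vs separate triples.

    Statistic N * ln(RSS0 / RSS1) with 3 degrees of freedom, where N is the
    pooled number of bins; returns (statistic, chi-square p-value).
    """
    set_x = np.asarray(set_x, float)
    genome_x = np.asarray(genome_x, float)
    pooled_x = np.concatenate([set_x, genome_x])
    pooled_y = np.concatenate([set_alpha, genome_alpha])
    if pooled_x.size <= 6:
        raise ValueError("fewer pooled bins than parameters")
    f0 = fit_asymptotic_alpha(pooled_x, pooled_y)
    f1a = fit_asymptotic_alpha(set_x, np.asarray(set_alpha, float))
    f1b = fit_asymptotic_alpha(genome_x, np.asarray(genome_alpha, float))
    rss0 = f0.rss
    rss1 = f1a.rss + f1b.rss
    n_tot = pooled_x.size
    stat = max(0.0, n_tot * np.log(max(rss0, 1e-300) / max(rss1, 1e-300)))
    return float(stat), float(stats.chi2.sf(stat, df=3))
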