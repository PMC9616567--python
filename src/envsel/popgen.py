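"""Diversity and differentiation statistics with gene-resampling bootstrap CIs.

Nucleotide diversity (pi) is computed over all callable sites with the
unbiased per-site heterozygosity; F_ST uses Weir & Cockerham variance
components summed over sites (ratio of sums, not mean of ratios); Tajima's D
uses the standard constants.  Confidence intervals for gene-set estimates
come from resampling genes with replacement and recomputing the statistic
from the resampled genes' summed components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass
class GeneStatResult:
    set_name: str
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n_genes: int
    reps: int


def nucleotide_diversity(
    counts: np.ndarray, n: np.ndarray | int, l_callable: float
) -> float:
    """pi per site: sum over variant sites of unbiased heterozygosity / L.

    Per site with derived (or minor) allele count c in n haplotypes the
    contribution is 2*c*(n-c) / (n*(n-1)), the average pairwise difference.
    Invariant sites contribute only through ``l_callable``.
    """
    if l_callable <= 0:
        raise ValueError("l_callable must be positive")
    counts = np.asarray(counts, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), counts.shape)
    if counts.size and (n < 2).any():
        raise ValueError("per-site sample size must be >= 2")
    if counts.size > l_callable:
        raise ValueError("more variant sites than callable sites")
    het = 2.0 * counts * (n - counts) / (n * (n - 1.0))
    return float(het.sum() / l_callable)


def pi_components(counts: np.ndarray, n: np.ndarray | int) -> tuple[float, float]:
    """(sum of per-site heterozygosities, number of sites) for one gene.

    Components add across genes; pi = sum(het) / sum(L), so they are the
    gene-level numerator/denominator for ratio-of-sums bootstrapping.
    """
    counts = np.asarray(counts, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), counts.shape)
    het = 2.0 * counts * (n - counts) / (n * (n - 1.0))
    return float(het.sum()), float(counts.size)


def weir_cockerham_components(
    genotypes: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Parameters
    ----------
    genotypes : one integer matrix per population, each (n_sites, n_ind)
        with entries 0/1/2 (alt-allele dosage) and NaN for missing.

    Returns arrays (a, b, c) of per-site components: a among populations,
    b among individuals within populations, c within individuals.  Sites
    where the components are undefined (fewer than two populations with
    data, or n_c = 0) are NaN.
    """
    r = len(genotypes)
    if r < 2:
        raise ValueError("need >=2 populations")
    mats = [np.asarray(g, dtype=float) for g in genotypes]
    n_sites = mats[0].shape[0]
    ni = np.empty((r, n_sites))
    pi_ = np.empty((r, n_sites))
    hi = np.empty((r, n_sites))
    for k, m in enumerate(mats):
        valid = ~np.isnan(m)
        ni[k] = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pi_[k] = np.nansum(m, axis=1) / (2.0 * ni[k])
            hi[k] = np.nansum(m == 1, axis=1) / ni[k]

    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = ni.sum(axis=0)
        nbar = nsum / r
        nc = (nsum - (ni**2).sum(axis=0) / nsum) / (r - 1.0)
        pbar = (ni * pi_).sum(axis=0) / nsum
        s2 = (ni * (pi_ - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (ni * hi).sum(axis=0) / nsum

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (ni < 1).sum(axis=0) > 0
    bad |= ~np.isfinite(nc) | (nc <= 0) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def weir_fst(
    genotypes: Sequence[np.ndarray], truncate: bool = False
) -> float:
    """Multi-population Weir & Cockerham F_ST = sum(a) / sum(a+b+c).

    Components are summed over sites (undefined sites skipped); negative
    estimates are reported as-is unless ``truncate`` is set.
    """
    a, b, c = weir_cockerham_components(genotypes)
    keep = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[keep] + b[keep] + c[keep]).sum()
    if denom == 0:
        raise ValueError("F_ST undefined: zero total variance")
    fst = float(a[keep].sum() / denom)
    return max(fst, 0.0) if truncate else fst


class MonomorphicSpectrumError(ValueError):
    """Tajima's D requested with no segregating sites."""


def tajimas_d(xi: np.ndarray, n: int, folded: bool = True) -> float:
    """Tajima's D from a single-class SFS with the standard constants.

    Works for folded or unfolded spectra: the per-bin pairwise-difference
    weight i*(n-i) is symmetric under i <-> n-i, so folding does not change
    theta_pi, and S is the bin total either way.
    """
    xi = np.asarray(xi, dtype=float)
    if n < 4:
        raise ValueError("n must be >= 4")
    S = xi.sum()
    if S <= 0:
        raise MonomorphicSpectrumError("no segregating sites: D undefined")
    nbins = n // 2 if folded else n - 1
    if xi.shape != (nbins,):
        raise ValueError(f"expected {nbins} bins for n={n}, folded={folded}")
    i = np.arange(1, nbins + 1)
    theta_pi = float((xi * 2.0 * i * (n - i) / (n * (n - 1.0))).sum())

    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((theta_pi - S / a1) / np.sqrt(var))


def gene_bootstrap(
    components: np.ndarray,
    stat_fn: Callable[[np.ndarray], float],
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    set_name: str = "",
    statistic: str = "",
) -> GeneStatResult:
    """Percentile bootstrap CI by resampling genes with replacement.

    ``components`` is an (n_genes, k) array of per-gene additive components;
    ``stat_fn`` maps the component sums (length-k vector) to the statistic,
    so the resampled statistic is a ratio of sums rather than a mean of
    per-gene ratios.  Replicates where the statistic is undefined are
    dropped (count reflected in nothing; percentiles use the rest).
    """
    comp = np.atleast_2d(np.asarray(components, dtype=float))
    n_genes = comp.shape[0]
    if n_genes < 1:
        raise ValueError("empty gene set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    estimate = float(stat_fn(comp.sum(axis=0)))
    vals = np.full(reps, np.nan)
    for r in range(reps):
        idx = rng.integers(0, n_genes, size=n_genes)
        try:
            vals[r] = stat_fn(comp[idx].sum(axis=0))
        except (ValueError, ZeroDivisionError):
            continue
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        lo = hi = estimate
    else:
        lo, hi = np.percentile(vals, [2.5, 97.5])
    return GeneStatResult(
        set_name=set_name,
        statistic=statistic,
        estimate=estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        n_genes=n_genes,
        reps=reps,
    )
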