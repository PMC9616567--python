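"""Genotype dosages and site frequency spectra.

Genotype uncertainty is carried as per-site, per-individual posterior
probabilities of the three diploid genotypes.  The expected genotype
(allelic dosage) E[G] = sum_g g * P(G=g) is the single point summary used
throughout: per-site allele counts are rounded sums of dosages over the
individuals of a population, and the counts are tallied into folded or
unfolded site frequency spectra for synonymous and nonsynonymous classes.

Parametric bootstrap replicates of a spectrum are drawn from a multinomial
over its frequency bins (plus fixed differences and the invariant
remainder), so each replicate preserves the callable-site total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SITE_CLASSES = ("synonymous", "nonsynonymous", "other")


@dataclass
class GenotypePosteriors:
    """Posterior genotype probabilities for a set of biallelic sites.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt, site_class, ancestral`` with ``pos``
        1-based and ``ancestral`` one of the two alleles or None/NaN.
    individuals : pandas.DataFrame
        Columns ``individual, population``.
    probs : numpy.ndarray
        Shape ``(n_sites, n_individuals, 3)``; each triple sums to 1.
        NaN rows mark missing calls.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 3 or probs.shape[2] != 3:
            raise ValueError("probs must have shape (n_sites, n_individuals, 3)")
        if probs.shape[0] != len(self.sites):
            raise ValueError("probs rows do not match sites")
        if probs.shape[1] != len(self.individuals):
            raise ValueError("probs columns do not match individuals")
        finite = ~np.isnan(probs).any(axis=2)
        if (probs[finite] < -1e-12).any():
            raise ValueError("negative genotype probability")
        sums = probs[finite].sum(axis=1)
        if sums.size and np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("genotype probability triples must sum to 1")
        bad = set(self.sites["site_class"]) - set(SITE_CLASSES)
        if bad:
            raise ValueError(f"unknown site classes: {sorted(bad)}")
        self.probs = probs


@dataclass
class SFSPair:
    """Synonymous + nonsynonymous site frequency spectra with site totals.

    Unfolded spectra have bins 1..n-1 (derived allele count); folded spectra
    have bins 1..n//2 (minor allele count).  ``l_s``/``l_n`` are callable
    site totals including invariant sites; ``d_s``/``d_n`` are fixed
    differences (meaningful for unfolded spectra with outgroup information).
    """

    n: int
    folded: bool
    xi_s: np.ndarray
    xi_n: np.ndarray
    l_s: float
    l_n: float
    d_s: float = 0.0
    d_n: float = 0.0

    def __post_init__(self) -> None:
        self.xi_s = np.asarray(self.xi_s, dtype=float)
        self.xi_n = np.asarray(self.xi_n, dtype=float)
        nbins = self.n // 2 if self.folded else self.n - 1
        for name, xi in (("xi_s", self.xi_s), ("xi_n", self.xi_n)):
            if xi.shape != (nbins,):
                raise ValueError(f"{name} must have {nbins} bins, got {xi.shape}")
            if (xi < 0).any():
                raise ValueError(f"{name} has negative counts")
        if self.xi_s.sum() > self.l_s or self.xi_n.sum() > self.l_n:
            raise ValueError("spectrum total exceeds callable sites")

    @property
    def frequencies(self) -> np.ndarray:
        """Allele frequencies x = i/n of the polymorphic bins."""
        nbins = self.n // 2 if self.folded else self.n - 1
        return np.arange(1, nbins + 1) / self.n


def expected_genotype(probs: Sequence[float]) -> float:
    """Allelic dosage E[G] = sum_g g * P(G=g) from a genotype-probability triple."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected a triple (P0, P1, P2)")
    if (p < 0).any():
        raise ValueError("negative genotype probability")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("genotype probabilities must sum to 1")
    return float(p[1] + 2.0 * p[2])


def dosage_matrix(gp: GenotypePosteriors) -> np.ndarray:
    """Expected-genotype matrix (sites x individuals); NaN where missing."""
    return gp.probs[:, :, 1] + 2.0 * gp.probs[:, :, 2]


def fold_sfs(sfs: SFSPair) -> SFSPair:
    """Fold an unfolded spectrum: bin i pools derived counts i and n-i."""
    if sfs.folded:
        return replace(sfs)
    return SFSPair(
        n=sfs.n,
        folded=True,
        xi_s=fold_counts(sfs.xi_s, sfs.n),
        xi_n=fold_counts(sfs.xi_n, sfs.n),
        l_s=sfs.l_s,
        l_n=sfs.l_n,
        d_s=sfs.d_s,
        d_n=sfs.d_n,
    )


def fold_counts(xi: np.ndarray, n: int) -> np.ndarray:
    """Fold unfolded bin counts (1..n-1) into minor-allele bins (1..n//2)."""
    xi = np.asarray(xi, dtype=float)
    half = n // 2
    out = np.zeros(half)
    for i in range(1, n):
        out[min(i, n - i) - 1] += xi[i - 1]
    return out


def build_sfs(
    gp: GenotypePosteriors,
    population: str,
    fold: bool = True,
    l_s: float | None = None,
    l_n: float | None = None,
) -> SFSPair:
    """Tally a population SFS pair from genotype posteriors.

    Per-site allele counts are the rounded (half-up) sums of expected
    genotypes over the population's individuals.  Sites with any missing
    individual are dropped entirely (the spectrum needs a fixed n).
    Monomorphic sites enter the callable totals; derived-fixed sites
    (unfolded, with an ancestral call) increment the fixed differences.
    ``l_s``/``l_n`` override the callable totals when the posteriors cover
    only variant sites.
    """
    mask = (gp.individuals["population"] == population).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"need >=2 individuals in population {population!r}")
    dos = dosage_matrix(gp)[:, mask]
    n = 2 * int(mask.sum())
    complete = ~np.isnan(dos).any(axis=1)
    sums = dos.sum(axis=1)
    counts = np.where(np.isnan(sums), 0, np.floor(sums + 0.5)).astype(int)  # ties round up

    sites = gp.sites
    anc = sites["ancestral"]
    has_anc = anc.notna().to_numpy() if hasattr(anc, "notna") else np.array(
        [a is not None for a in anc]
    )
    if not fold:
        if not has_anc.any():
            raise ValueError("unfolded SFS requested but no ancestral calls")
        derived_is_alt = (sites["ancestral"] == sites["ref"]).to_numpy()
        usable = complete & has_anc
    else:
        usable = complete

    nbins = n // 2 if fold else n - 1
    out = {"synonymous": np.zeros(nbins), "nonsynonymous": np.zeros(nbins)}
    ltot = {"synonymous": 0.0, "nonsynonymous": 0.0}
    dfix = {"synonymous": 0.0, "nonsynonymous": 0.0}
    classes = sites["site_class"].to_numpy()
    for idx in np.nonzero(usable)[0]:
        cls = classes[idx]
        if cls == "other":
            continue
        c = counts[idx]
        if not fold:
            c = c if derived_is_alt[idx] else n - c
        ltot[cls] += 1
        if c == 0:
            continue
        if c == n:
            if not fold:
                dfix[cls] += 1
            continue
        b = min(c, n - c) if fold else c
        out[cls][b - 1] += 1

    return SFSPair(
        n=n,
        folded=fold,
        xi_s=out["synonymous"],
        xi_n=out["nonsynonymous"],
        l_s=float(l_s) if l_s is not None else ltot["synonymous"],
        l_n=float(l_n) if l_n is not None else ltot["nonsynonymous"],
        d_s=dfix["synonymous"],
        d_n=dfix["nonsynonymous"],
    )


def _bootstrap_class(
    xi: np.ndarray, d: float, L: float, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial resampling of one site class.

    Categories are the polymorphic bins, the fixed-difference class and the
    invariant remainder; trials equal the callable-site total L, so every
    replicate preserves L exactly.
    """
    trials = int(round(L))
    seg = float(xi.sum())
    invariant = L - seg - d
    if invariant < -1e-9:
        raise ValueError("spectrum plus divergence exceeds callable sites")
    probs = np.concatenate([xi, [d, max(invariant, 0.0)]]) / trials
    draws = rng.multinomial(trials, probs, size=reps)
    return draws[:, : xi.size].astype(float), draws[:, xi.size].astype(float)


def bootstrap_sfs(sfs: SFSPair, reps: int, seed: int | np.random.Generator) -> list[SFSPair]:
    """Multinomial parametric-bootstrap replicates of an SFS pair.

    Synonymous and nonsynonymous classes are resampled independently; fixed
    differences are resampled together with the bins so that downstream
    divergence-based statistics get bootstrap variation too.
    """
    if reps < 1:
        raise ValueError("reps must be >=1")
    if sfs.xi_s.sum() + sfs.xi_n.sum() == 0:
        raise ValueError("cannot bootstrap an empty SFS")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, ds = _bootstrap_class(sfs.xi_s, sfs.d_s, sfs.l_s, reps, rng)
    xn, dn = _bootstrap_class(sfs.xi_n, sfs.d_n, sfs.l_n, reps, rng)
    return [
        SFSPair(
            n=sfs.n,
            folded=sfs.folded,
            xi_s=xs[r],
            xi_n=xn[r],
            l_s=sfs.l_s,
            l_n=sfs.l_n,
            d_s=ds[r],
            d_n=dn[r],
        )
        for r in range(reps)
    ]


def watterson_theta(xi: np.ndarray, n: int, L: float) -> float:
    """Watterson's theta per site from segregating-site count S = sum(xi)."""
    if L <= 0:
        raise ValueError("L must be positive")
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(np.sum(xi) / (a1 * L))
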