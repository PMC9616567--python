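"""Gene-set enrichment, sweep-outlier thresholding and conservation rescaling.

Fisher's exact tests with log2 odds ratios for candidate-set vs feature
associations (CNSs, H2A.Z sites, TE superfamilies, sweeps), hypergeometric
GO enrichment with Q-values, selective-sweep calling against the 99th
percentile of neutral simulations, and 0-1 rescaling of GERP rejected-
substitution scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues


@dataclass
class EnrichmentResult:
    set_name: str
    feature_name: str
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    log2_or: float
    p: float
    ci_low: float | None = None
    ci_high: float | None = None
    haldane: bool = False


def _table(set_genes: set, feature_genes: set, universe: set) -> tuple[int, int, int, int]:
    if not universe:
        raise ValueError("empty universe")
    if not set_genes <= universe or not feature_genes <= universe:
        raise ValueError("set and feature must be subsets of the universe")
    a = len(set_genes & feature_genes)
    b = len(set_genes - feature_genes)
    c = len(feature_genes - set_genes)
    d = len(universe) - a - b - c
    return a, b, c, d


def fisher_enrichment(
    set_genes,
    feature_genes,
    universe,
    set_name: str = "set",
    feature_name: str = "feature",
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 set x feature table.

    The odds ratio is (a*d)/(b*c), with a Haldane 0.5 correction of every
    cell when any cell is zero (flagged).  Optional 95% CI for the OR by
    case resampling of universe genes (1000 reps typical).
    """
    set_genes, feature_genes, universe = set(set_genes), set(feature_genes), set(universe)
    a, b, c, d = _table(set_genes, feature_genes, universe)
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    haldane = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    res = EnrichmentResult(
        set_name=set_name,
        feature_name=feature_name,
        table=(a, b, c, d),
        odds_ratio=float(odds),
        log2_or=float(np.log2(odds)),
        p=float(p),
        haldane=haldane,
    )
    if n_bootstrap > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        genes = np.array(sorted(universe), dtype=object)
        in_set = np.isin(genes, sorted(set_genes))
        in_feat = np.isin(genes, sorted(feature_genes))
        n = genes.size
        ors = np.empty(n_bootstrap)
        for r in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            s, f = in_set[idx], in_feat[idx]
            ra = np.count_nonzero(s & f)
            rb = np.count_nonzero(s & ~f)
            rc = np.count_nonzero(~s & f)
            rd = n - ra - rb - rc
            if min(ra, rb, rc, rd) == 0:
                ra, rb, rc, rd = ra + 0.5, rb + 0.5, rc + 0.5, rd + 0.5
            ors[r] = (ra * rd) / (rb * rc)
        res.ci_low, res.ci_high = map(float, np.percentile(ors, [2.5, 97.5]))
    return res


def hypergeometric_go(
    term_map: dict[str, set] | pd.DataFrame,
    candidate_genes,
    q_method: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per GO term with Q-values.

    ``term_map`` maps term -> annotated genes (or a DataFrame with columns
    ``gene, term``).  The universe is the union of annotated genes (genes
    without any term are excluded from both margins); candidates outside the
    universe are dropped.
    """
    if isinstance(term_map, pd.DataFrame):
        term_map = {t: set(sub["gene"]) for t, sub in term_map.groupby("term")}
    if not term_map:
        raise ValueError("empty term map")
    universe = set().union(*term_map.values())
    cand = set(candidate_genes) & universe
    M, N = len(universe), len(cand)
    rows = []
    for term, genes in sorted(term_map.items()):
        K = len(genes)
        k = len(genes & cand)
        p = stats.hypergeom.sf(k - 1, M, K, N)
        rows.append((term, k, K, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"]).set_index("term")
    out["q"] = adjust_pvalues(out["p"].to_numpy(), "q", q_method=q_method)
    return out


@dataclass
class SweepScore:
    gene: str
    score: float
    null_quantile_99: float
    is_sweep: bool


def sweep_outliers(
    gene_scores: dict[str, float] | pd.Series,
    null_scores: np.ndarray,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Flag genes whose composite selection score exceeds the simulated null.

    The threshold is the empirical ``percentile`` (linear interpolation) of
    the neutral-simulation scores; genes are flagged when strictly greater.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size < 100:
        raise ValueError("need >=100 null scores")
    if not np.isfinite(null_scores).all():
        raise ValueError("null scores must be finite")
    scores = pd.Series(gene_scores, dtype=float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("gene scores must be finite")
    thr = float(np.percentile(null_scores, percentile))
    return pd.DataFrame(
        {
            "score": scores,
            "null_quantile_99": thr,
            "is_sweep": scores > thr,
        }
    )


def max_score_near_gene(
    windows: pd.DataFrame, genes: pd.DataFrame, margin: int = 2000
) -> pd.Series:
    """Per-gene sweep score: max window statistic within +-margin of the gene body.

    ``windows`` has columns ``chrom, start, end, score``; genes without any
    window in range get NaN.
    """
    out = pd.Series(np.nan, index=genes["gene"], dtype=float)
    by_chrom = {c: sub for c, sub in windows.groupby("chrom")}
    for row in genes.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        hit = (sub["end"] >= row.start - margin) & (sub["start"] <= row.end + margin)
        if hit.any():
            out.at[row.gene] = float(sub.loc[hit, "score"].max())
    return out


def rescale_gerp(
    rs: np.ndarray, rs_min: np.ndarray, rs_max: np.ndarray
) -> np.ndarray:
    """Rescale GERP RS scores to [0, 1] using each site's attainable range."""
    rs, rs_min, rs_max = (np.asarray(x, dtype=float) for x in (rs, rs_min, rs_max))
    if (rs_max <= rs_min).any():
        raise ValueError("degenerate RS range (max <= min)")
    return np.clip((rs - rs_min) / (rs_max - rs_min), 0.0, 1.0)


def upstream_feature_overlap(
    genes: pd.DataFrame, features: pd.DataFrame, window: int = 1000
) -> pd.Series:
    """True iff a feature intersects the strand-aware 1 kb upstream interval.

    The upstream interval ends just before the TSS and is truncated at the
    contig start rather than erroring.
    """
    out = pd.Series(False, index=genes["gene"], dtype=bool)
    by_chrom = {c: sub for c, sub in features.groupby("chrom")}
    for row in genes.itertuples():
        if row.strand == "-":
            lo, hi = row.end + 1, row.end + window
        else:
            lo, hi = max(1, row.start - window), row.start - 1
        if hi < lo:
            continue
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        out.at[row.gene] = bool(((sub["end"] >= lo) & (sub["start"] <= hi)).any())
    return out
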