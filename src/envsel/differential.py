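"""Differential expression and differential methylation testing.

Expression: per-gene negative-binomial GLMs (log link, median-of-ratios size
factors as offsets, a single per-gene dispersion estimated by maximum
likelihood under the full model) compared by likelihood-ratio tests across
the model ladder

    field:        Expression ~ population + field   vs  ~ population
    population:   Expression ~ field + population   vs  ~ field
    interaction:  Expression ~ field + population + field:population
                                                    vs  ~ field + population

Methylation: the diploid methylome is treated as two alleles.  Per gene and
individual the methylated allelic dosage is 2 x the sum of per-cytosine
methylation proportions (and the unmethylated dosage its complement), and
the dosages are compared with binomial-weighted logistic regressions over
the same ladder, with the sample's non-CG methylation rate (CH%) as a
covariate for CG tests.  Fractional dosages are handled as weighted
likelihood on proportions (quasi-likelihood); LRT p-values can be corrected
with the genomic inflation factor.

Multiple testing: Bonferroni for the field/population expression tests,
FDR Q-values (Benjamini-Hochberg by default, Storey optional) elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

TESTS = ("field", "population", "interaction")


# ---------------------------------------------------------------------------
# design matrices

def _design_matrix(design: pd.DataFrame, terms: list[str],
                   covariate: np.ndarray | None = None) -> np.ndarray:
    """Treatment-coded design matrix with intercept for the given terms."""
    cols = [np.ones(len(design))]
    main = {}
    for term in terms:
        if term == "interaction":
            continue
        d = pd.get_dummies(design[term], drop_first=True).to_numpy(dtype=float)
        main[term] = d
        cols.append(d)
    if "interaction" in terms:
        f = main["field"]
        p = main["population"]
        inter = (f[:, :, None] * p[:, None, :]).reshape(len(design), -1)
        cols.append(inter)
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float)[:, None])
    return np.column_stack(cols)


def model_terms(test: str) -> tuple[list[str], list[str]]:
    """Full and reduced model terms for one ladder row."""
    if test == "field":
        return ["population", "field"], ["population"]
    if test == "population":
        return ["field", "population"], ["field"]
    if test == "interaction":
        return ["field", "population", "interaction"], ["field", "population"]
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# expression

def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style median-of-ratios size factors.

    The geometric-mean reference uses genes with all-nonzero counts.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has all-nonzero counts; cannot normalize")
    ref = np.exp(np.log(mat[nonzero]).mean(axis=1))
    return np.median(mat[nonzero] / ref[:, None], axis=0)


def filter_expressed(counts: pd.DataFrame, min_median: float = 1.0) -> pd.DataFrame:
    """Keep genes with median count across samples > ``min_median``."""
    if counts.shape[0] == 0:
        raise ValueError("empty count matrix")
    kept = counts[counts.median(axis=1) > min_median]
    if kept.shape[0] == 0:
        raise ValueError("all genes removed by the median-count filter")
    return kept


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative-binomial log likelihood with variance mu + alpha*mu^2."""
    size = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, size, size / (size + mu))))


def _fit_glm_nb(y, X, offset, alpha):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def _profile_dispersion(y, X, offset, bounds=(1e-8, 10.0)) -> float:
    """Per-gene dispersion by Cox-Reid adjusted profile maximum likelihood.

    The adjustment term -0.5*logdet(X' W X) removes the downward bias of the
    plain MLE caused by the fitted mean parameters; without it the LRTs are
    anticonservative at these sample sizes.  No shrinkage across genes.
    """
    def neg(log_a):
        a = np.exp(log_a)
        try:
            res = _fit_glm_nb(y, X, offset, a)
        except Exception:
            return 1e12
        mu = res.mu
        w = mu / (1.0 + a * mu)  # NB log-link working weights
        _, logdet = np.linalg.slogdet(X.T @ (w[:, None] * X))
        return -(_nb_loglik(y, mu, a) - 0.5 * logdet)

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-2, "maxiter": 40},
    )
    return float(np.exp(res.x))


def deg_lrt(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    test: str,
    q_method: str = "bh",
) -> pd.DataFrame:
    """Per-gene NB-GLM likelihood-ratio tests for one ladder row.

    Returns a DataFrame indexed by gene with columns ``lrt_stat, df, p,
    p_bonferroni, q, flagged, converged, dispersion``.  The LRT statistic is
    referred to an F distribution with (df, residual df) -- see the inline
    note -- rather than a chi-square.  Interaction tests are flagged at
    Q < 0.05, field/population at Bonferroni p < 0.05.
    Genes whose fits do not converge keep p = 1 with ``converged = False``
    (retained in the multiplicity denominator).
    """
    full_terms, red_terms = model_terms(test)
    sf = size_factors(counts)
    offset = np.log(sf)
    X_full = _design_matrix(design, full_terms)
    X_red = _design_matrix(design, red_terms)
    rank_full = np.linalg.matrix_rank(X_full)
    df_diff = rank_full - np.linalg.matrix_rank(X_red)
    df_resid = len(design) - rank_full

    genes = counts.index
    stat = np.zeros(len(genes))
    pvals = np.ones(len(genes))
    converged = np.ones(len(genes), dtype=bool)
    disp = np.full(len(genes), np.nan)
    mat = counts.to_numpy(dtype=float)
    for g in range(len(genes)):
        y = mat[g]
        try:
            alpha = _profile_dispersion(y, X_full, offset)
            full = _fit_glm_nb(y, X_full, offset, alpha)
            red = _fit_glm_nb(y, X_red, offset, alpha)
            lr = 2.0 * (_nb_loglik(y, full.mu, alpha) - _nb_loglik(y, red.mu, alpha))
        except Exception:
            converged[g] = False
            continue
        if not np.isfinite(lr):
            converged[g] = False
            continue
        disp[g] = alpha
        stat[g] = max(lr, 0.0)
        # F-type reference distribution: the per-gene dispersion is estimated,
        # not known, and a chi-square reference is anticonservative at these
        # sample sizes (worst at high counts where dispersion dominates).
        pvals[g] = stats.f.sf(stat[g] / df_diff, df_diff, df_resid)

    out = pd.DataFrame(
        {
            "test": test,
            "lrt_stat": stat,
            "df": df_diff,
            "p": pvals,
            "p_bonferroni": adjust_pvalues(pvals, "bonferroni"),
            "q": adjust_pvalues(pvals, "q", q_method=q_method),
            "converged": converged,
            "dispersion": disp,
        },
        index=genes,
    )
    if test == "interaction":
        out["flagged"] = out["q"] < 0.05
    else:
        out["flagged"] = out["p_bonferroni"] < 0.05
    return out


# ---------------------------------------------------------------------------
# methylation

def methylation_dosage(
    table: pd.DataFrame,
    individuals: list[str],
    context_class: str = "CG",
    min_reads: int = 4,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Allelic methylation dosages for one gene's cytosine records.

    ``table`` holds the cytosine report rows of a single gene (columns
    ``pos, context, meth, total, individual``).  Sites with <= ``min_reads-1``
    reads are treated as missing; cytosines missing in >= ``max_missing`` of
    individuals are removed.  Per individual, the methylated dosage is
    2 x the sum of methylation proportions over its covered cytosines, the
    unmethylated dosage its complement, so meth + unmeth = 2 x n_cytosines.
    """
    if context_class == "CG":
        sub = table[table["context"] == "CG"]
    elif context_class == "CH":
        sub = table[table["context"].isin(("CHG", "CHH"))]
    else:
        raise ValueError("context_class must be 'CG' or 'CH'")
    sub = sub[sub["total"] >= min_reads]
    if sub.empty:
        raise ValueError("no cytosines survive the read-depth filter")
    prop = sub.assign(prop=sub["meth"] / sub["total"]).pivot_table(
        index="pos", columns="individual", values="prop", aggfunc="mean"
    ).reindex(columns=individuals)
    missing_frac = prop.isna().mean(axis=1)
    prop = prop[missing_frac < max_missing]
    if prop.empty:
        raise ValueError("no cytosines survive the missing-data filter")
    n_cyt = prop.notna().sum(axis=0).to_numpy(dtype=float)
    meth = 2.0 * prop.sum(axis=0, skipna=True).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "individual": individuals,
            "meth": meth,
            "unmeth": 2.0 * n_cyt - meth,
            "n_cytosines": n_cyt.astype(int),
        }
    )


def gene_methylation_dosages(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    individuals: list[str],
    context_class: str = "CG",
    min_reads: int = 4,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Dosages for every gene interval (long format, genes without data skipped)."""
    out = []
    by_chrom = {c: t.sort_values("pos") for c, t in table.groupby("chrom")}
    for row in genes.itertuples():
        sub_all = by_chrom.get(row.chrom)
        if sub_all is None:
            continue
        lo = np.searchsorted(sub_all["pos"].to_numpy(), row.start, side="left")
        hi = np.searchsorted(sub_all["pos"].to_numpy(), row.end, side="right")
        sub = sub_all.iloc[lo:hi]
        if sub.empty:
            continue
        try:
            d = methylation_dosage(sub, individuals, context_class,
                                   min_reads, max_missing)
        except ValueError:
            continue
        d.insert(0, "gene", row.gene)
        out.append(d)
    if not out:
        return pd.DataFrame(columns=["gene", "individual", "meth", "unmeth", "n_cytosines"])
    return pd.concat(out, ignore_index=True)


def promoter_intervals(genes: pd.DataFrame, window: int = 1000) -> pd.DataFrame:
    """Strand-aware 1 kb upstream intervals, truncated at the contig edge."""
    out = genes.copy()
    plus = out["strand"] != "-"
    out.loc[plus, "end"] = genes.loc[plus, "start"] - 1
    out.loc[plus, "start"] = np.maximum(1, genes.loc[plus, "start"] - window)
    out.loc[~plus, "start"] = genes.loc[~plus, "end"] + 1
    out.loc[~plus, "end"] = genes.loc[~plus, "end"] + window
    return out


def _fit_binom(frac, X, w):
    model = sm.GLM(frac, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def dmg_lrt(
    dosages: pd.DataFrame,
    design: pd.DataFrame,
    test: str,
    context_class: str = "CG",
    ch_percent: pd.Series | None = None,
    min_cytosines: int = 10,
    q_method: str = "bh",
    inflation_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene allelic-dosage logistic LRTs for one ladder row.

    ``dosages`` is the long table from :func:`gene_methylation_dosages`;
    genes need >= ``min_cytosines`` cytosines (minimum over individuals with
    data).  For CG tests the per-sample genome-wide CH% methylation rate is
    included as a covariate in full and reduced models.  Flagging is at
    Q < 0.05; optionally the p-values are corrected with the genomic
    inflation factor before Q-value computation.
    """
    if context_class == "CG" and ch_percent is None:
        raise ValueError("CG tests require the CH%% covariate (ch_percent)")
    full_terms, red_terms = model_terms(test)
    design = design.set_index("sample") if "sample" in design.columns else design

    results = []
    for gene, sub in dosages.groupby("gene", sort=True):
        if sub["n_cytosines"].min() < min_cytosines:
            continue
        sub = sub.set_index("individual").reindex(design.index).dropna(
            subset=["meth", "unmeth"])
        d = design.loc[sub.index]
        cov = None
        if context_class == "CG":
            cov = ch_percent.reindex(sub.index).to_numpy()
        X_full = _design_matrix(d, full_terms, covariate=cov)
        X_red = _design_matrix(d, red_terms, covariate=cov)
        total = (sub["meth"] + sub["unmeth"]).to_numpy()
        frac = sub["meth"].to_numpy() / total
        converged = True
        try:
            full = _fit_binom(frac, X_full, total)
            red = _fit_binom(frac, X_red, total)
            lr = max(0.0, 2.0 * (full.llf - red.llf))
        except Exception:
            lr, converged = 0.0, False
        df_diff = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_red)
        results.append((gene, lr, df_diff, converged))
    if not results:
        raise ValueError("no genes pass the cytosine filter")
    out = pd.DataFrame(results, columns=["gene", "lrt_stat", "df", "converged"]).set_index("gene")
    out.insert(0, "test", test)
    df_diff = int(out["df"].iloc[0])
    lam = np.nan
    if inflation_correct:
        corrected, lam = genomic_inflation_correct(
            out["lrt_stat"].to_numpy(), df_diff)
        out["p"] = corrected
    else:
        out["p"] = stats.chi2.sf(out["lrt_stat"], out["df"])
    out.loc[~out["converged"], "p"] = 1.0
    out["p_bonferroni"] = adjust_pvalues(out["p"].to_numpy(), "bonferroni")
    out["q"] = adjust_pvalues(out["p"].to_numpy(), "q", q_method=q_method)
    out["flagged"] = out["q"] < 0.05
    out.attrs["inflation_lambda"] = lam
    return out


def responsive_fraction(n_responsive: int, n_expressed: int) -> float:
    """Percentage of expressed genes called environmentally responsive.

    Rounded to the nearest whole percent, the precision at which such
    fractions are reported.
    """
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    if not 0 <= n_responsive <= n_expressed:
        raise ValueError("n_responsive out of range")
    return float(round(100.0 * n_responsive / n_expressed))


def genomic_inflation_correct(lrt_stats: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Genomic-control correction of LRT statistics.

    lambda = median(stat) / median(chi2_df); when lambda > 1 the statistics
    are divided by lambda before p-value computation.  Returns (p, lambda).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    lrt_stats = np.asarray(lrt_stats, dtype=float)
    if lrt_stats.size < 10:
        raise ValueError("need >=10 statistics to estimate inflation")
    lam = float(np.median(lrt_stats) / stats.chi2.ppf(0.5, df))
    corrected = lrt_stats / lam if lam > 1.0 else lrt_stats
    return stats.chi2.sf(corrected, df), lam


def adjust_pvalues(p: np.ndarray, method: str, q_method: str = "bh") -> np.ndarray:
    """Bonferroni or FDR Q-value adjustment.

    ``method='q'`` uses Benjamini-Hochberg by default; ``q_method='storey'``
    scales BH by a pi0 estimate (lambda = 0.5 histogram estimator), which is
    unstable for small m and therefore not the default.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "q":
        raise ValueError("method must be 'bonferroni' or 'q'")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(1.0, ranked)
    if q_method == "storey":
        lam = 0.5
        pi0 = min(1.0, (p > lam).mean() / (1.0 - lam)) if m else 1.0
        q = np.minimum(1.0, q * max(pi0, 1.0 / m))
    elif q_method != "bh":
        raise ValueError("q_method must be 'bh' or 'storey'")
    return q
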