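"""Methylation summaries and transposable-element utilities.

Covers genome-wide methylation levels per context, bisulfite conversion
efficiency from the (naturally unmethylated) chloroplast, meta-gene /
meta-TE methylation profiles, TE-family expression counting from read
assignments, read-support TE genotype discretization, class/superfamily
composition, and nearest-feature distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")


def methylation_level(
    table: pd.DataFrame,
    context: str | None = None,
    group: str | None = None,
) -> float | pd.Series:
    """Read-weighted mean methylation proportion.

    Computed as sum(meth) / sum(total) over the selected records, i.e. the
    per-site proportions weighted by read counts.  ``context`` restricts to
    one cytosine context ('CH' groups CHG+CHH); ``group`` names a column
    (e.g. ``individual``) and switches to a per-group Series.
    """
    sub = table
    if context is not None:
        if context == "CH":
            sub = sub[sub["context"].isin(("CHG", "CHH"))]
        elif context in CONTEXTS:
            sub = sub[sub["context"] == context]
        else:
            raise ValueError(f"unknown context {context!r}")
    if sub.empty:
        raise ValueError("empty selection")
    if group is None:
        return float(sub["meth"].sum() / sub["total"].sum())
    agg = sub.groupby(group)[["meth", "total"]].sum()
    return agg["meth"] / agg["total"]


def ch_percent(table: pd.DataFrame) -> pd.Series:
    """Per-individual genome-wide non-CG methylation rate (CG-test covariate)."""
    sub = table[table["context"].isin(("CHG", "CHH"))]
    agg = sub.groupby("individual")[["meth", "total"]].sum()
    return agg["meth"] / agg["total"]


def conversion_efficiency(
    table: pd.DataFrame, chloroplast: str = "chloroplast"
) -> pd.Series:
    """Bisulfite conversion efficiency per context from chloroplast records.

    The chloroplast is naturally unmethylated, so apparent methylation there
    measures conversion failure: efficiency = 1 - sum(meth)/sum(total).
    """
    sub = table[table["chrom"] == chloroplast]
    if sub.empty:
        raise ValueError(f"no records on chloroplast contig {chloroplast!r}")
    agg = sub.groupby("context")[["meth", "total"]].sum()
    return 1.0 - agg["meth"] / agg["total"]


def metagene_profile(
    table: pd.DataFrame,
    features: pd.DataFrame,
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 10,
    context: str | None = None,
) -> pd.DataFrame:
    """Meta-feature methylation profile (upstream flank, body, downstream flank).

    Feature bodies are mapped to relative coordinates 0-1 in ``body_bins``
    bins; flanks use absolute bp bins.  Minus-strand features are reversed
    so that bin 0 is always the 5' end.  Returns a DataFrame with columns
    ``segment, bin, level, n_sites`` where level is the unweighted mean of
    per-site proportions; features shorter than one bp per body bin are
    skipped (count in ``attrs['skipped']``).
    """
    sub = table
    if context is not None:
        sub = sub[sub["context"].isin(("CHG", "CHH"))] if context == "CH" else sub[
            sub["context"] == context]
    acc = {seg: (np.zeros(nb), np.zeros(nb, dtype=int))
           for seg, nb in (("upstream", flank_bins), ("body", body_bins),
                           ("downstream", flank_bins))}
    skipped = 0
    by_chrom = {c: t.sort_values("pos") for c, t in sub.groupby("chrom")}
    for ft in features.itertuples():
        length = ft.end - ft.start + 1
        if length < body_bins:
            skipped += 1
            continue
        t = by_chrom.get(ft.chrom)
        if t is None:
            continue
        pos = t["pos"].to_numpy()
        lo = np.searchsorted(pos, ft.start - flank_bp, side="left")
        hi = np.searchsorted(pos, ft.end + flank_bp, side="right")
        window = t.iloc[lo:hi]
        if window.empty:
            continue
        p = window["pos"].to_numpy()
        prop = (window["meth"] / window["total"]).to_numpy()
        minus = ft.strand == "-"
        # signed distance from feature 5' start, in feature orientation
        rel = (ft.end - p) if minus else (p - ft.start)
        tail = (p - ft.end) if not minus else (ft.start - p)
        in_body = (rel >= 0) & (rel < length)
        upstream = rel < 0
        downstream = tail > 0

        b = np.floor(rel[in_body] / length * body_bins).astype(int)
        np.add.at(acc["body"][0], b, prop[in_body])
        np.add.at(acc["body"][1], b, 1)
        ub = np.floor((rel[upstream] + flank_bp) / flank_bp * flank_bins).astype(int)
        ok = (ub >= 0) & (ub < flank_bins)
        np.add.at(acc["upstream"][0], ub[ok], prop[upstream][ok])
        np.add.at(acc["upstream"][1], ub[ok], 1)
        db = np.floor((tail[downstream] - 1) / flank_bp * flank_bins).astype(int)
        ok = (db >= 0) & (db < flank_bins)
        np.add.at(acc["downstream"][0], db[ok], prop[downstream][ok])
        np.add.at(acc["downstream"][1], db[ok], 1)

    rows = []
    for seg in ("upstream", "body", "downstream"):
        tot, cnt = acc[seg]
        with np.errstate(invalid="ignore"):
            level = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        for k in range(len(tot)):
            rows.append((seg, k, level[k], cnt[k]))
    out = pd.DataFrame(rows, columns=["segment", "bin", "level", "n_sites"])
    out.attrs["skipped"] = skipped
    return out


def te_family_counts(
    assignments: pd.DataFrame, families: list[str] | None = None
) -> pd.DataFrame:
    """TE-family read counts from read-to-feature assignments.

    ``assignments`` has one row per (read_id, sample, feature) overlap with
    columns ``read_id, sample, feature_kind ('gene'|'TE'), family``.  A read
    counts once for family F iff every feature it overlaps is a TE of family
    F: reads touching any gene, or TEs of two or more families, are excluded
    (multi-mapping within one family is allowed).
    """
    req = {"read_id", "sample", "feature_kind", "family"}
    if not req.issubset(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(req)}")
    known = set(families) if families is not None else None
    te_rows = assignments["feature_kind"] == "TE"
    if known is not None:
        bad = set(assignments.loc[te_rows, "family"]) - known
        if bad:
            raise ValueError(f"unknown TE families: {sorted(bad)}")
    grp = assignments.groupby(["sample", "read_id"], sort=False)
    summary = grp.agg(
        any_gene=("feature_kind", lambda k: (k == "gene").any()),
        n_families=("family", lambda f: f.dropna().nunique()),
        family=("family", "first"),
    ).reset_index()
    keep = (~summary["any_gene"]) & (summary["n_families"] == 1)
    counted = summary[keep]
    out = counted.groupby(["family", "sample"]).size().unstack(fill_value=0)
    return out


def discretize_te_genotypes(
    table: pd.DataFrame,
    min_coverage: int = 6,
    het_range: tuple[float, float] = (0.15, 0.85),
) -> pd.DataFrame:
    """Read-support TE genotypes: >0.85 homozygote (2), 0.85-0.15 heterozygote
    (1), <0.15 absent (0); coverage < 6x is missing.

    The published boundaries are assigned to the heterozygote (inclusive
    ends).  Returns an insertion x individual matrix with NaN for missing.
    """
    sup = table["support"].to_numpy(dtype=float)
    if ((sup < 0) | (sup > 1)).any():
        raise ValueError("read-support proportions must lie in [0, 1]")
    lo, hi = het_range
    geno = np.where(sup > hi, 2.0, np.where(sup >= lo, 1.0, 0.0))
    geno = np.where(table["coverage"].to_numpy() < min_coverage, np.nan, geno)
    out = table.assign(genotype=geno).pivot_table(
        index="insertion", columns="individual", values="genotype",
        aggfunc="first", dropna=False,
    )
    return out


def te_composition(
    genotypes: pd.DataFrame,
    taxonomy: pd.DataFrame,
    by: str = "te_class",
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dosage-weighted TE class/superfamily composition with bootstrap CIs.

    The share of each level is the summed genotype dosage of its insertions
    over the total dosage; CIs resample insertions with replacement.
    ``taxonomy`` maps ``insertion`` to ``family/superfamily/te_class``.
    """
    dose = np.nansum(genotypes.to_numpy(dtype=float), axis=1)
    labels = taxonomy.set_index("insertion")[by].reindex(genotypes.index)
    if labels.isna().any():
        raise ValueError("taxonomy does not cover all insertions")
    total = dose.sum()
    if total == 0:
        raise ValueError("no insertion copies present")
    levels = sorted(labels.unique())
    onehot = np.column_stack([(labels == lv).to_numpy(float) for lv in levels])
    est = (dose @ onehot) / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ins = dose.size
    boots = np.empty((n_bootstrap, len(levels)))
    for r in range(n_bootstrap):
        idx = rng.integers(0, n_ins, size=n_ins)
        d = dose[idx]
        boots[r] = (d @ onehot[idx]) / max(d.sum(), 1e-300)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"level": levels, "proportion": est, "ci_low": lo, "ci_high": hi}
    ).set_index("level")


def distance_to_nearest(
    features_a: pd.DataFrame, features_b: pd.DataFrame
) -> pd.Series:
    """Gap (bp) from each a-feature to its nearest b-feature, 0 if overlapping.

    Intervals are 1-based inclusive; chromosomes without any b-feature give
    NaN (signalled missing, not infinity).
    """
    if features_b.empty:
        raise ValueError("empty b-feature set")
    out = pd.Series(np.nan, index=features_a.index, dtype=float)
    b_by_chrom = {
        c: sub.sort_values("start")[["start", "end"]].to_numpy()
        for c, sub in features_b.groupby("chrom")
    }
    for idx, row in features_a.iterrows():
        arr = b_by_chrom.get(row["chrom"])
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        gap_right = starts - row["end"] - 1  # b entirely to the right
        gap_left = row["start"] - ends - 1  # b entirely to the left
        gaps = np.maximum(np.maximum(gap_right, gap_left), 0)
        overlap = (starts <= row["end"]) & (ends >= row["start"])
        out.at[idx] = 0.0 if overlap.any() else float(gaps.min())
    return out


def subsample_te_individuals(
    table: pd.DataFrame,
    n_per_population: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Depth-equalisation stand-in: keep n randomly chosen individuals per
    population from the insertion table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = []
    for pop, sub in table.groupby("population"):
        inds = np.sort(sub["individual"].unique())
        if len(inds) < n_per_population:
            raise ValueError(f"population {pop} has fewer than {n_per_population} individuals")
        chosen = rng.choice(inds, size=n_per_population, replace=False)
        keep.append(sub[sub["individual"].isin(chosen)])
    return pd.concat(keep, ignore_index=True)


def te_presence_sfs(genotypes: pd.DataFrame, individuals: list[str]) -> tuple[np.ndarray, int]:
    """Folded presence/absence SFS over TE insertions for Tajima's D.

    Each insertion is one biallelic locus; insertions with any missing
    genotype among the chosen individuals, or monomorphic ones, are dropped.
    Returns (folded bin counts, n haplotypes).
    """
    sub = genotypes[individuals]
    complete = sub.notna().all(axis=1)
    counts = sub[complete].sum(axis=1).to_numpy(dtype=int)
    n = 2 * len(individuals)
    seg = counts[(counts > 0) & (counts < n)]
    minor = np.minimum(seg, n - seg)
    xi = np.bincount(minor, minlength=n // 2 + 1)[1: n // 2 + 1].astype(float)
    return xi, n
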