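"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: site frequency
spectra shaped by an equilibrium gamma DFE plus an adaptive fixation
fraction, genotype posteriors (softened one-hot triples), Bismark-style
cytosine-report methylation data under a 3 populations x 2 fields factorial
design, negative-binomial expression counts, and TE insertion tables with
per-individual read-support proportions.  All generators are driven by a
seeded numpy Generator: identical seeds give bit-identical outputs.

The methylation generator works at the level of epialleles: each cytosine of
a diploid individual carries 0, 1 or 2 methylated alleles drawn
Binomial(2, p), and reads sample the resulting allelic proportion (plus a
bisulfite conversion-failure floor).  The gene-level allelic dosage
(2 x sum of methylation proportions) is then itself binomial in
2 x n_cytosines trials, which is exactly the model the differential
methylation test assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .selection import dfe_bin_proportions, expected_sfs_gamma, mean_fixation_factor
from .sfs import GenotypePosteriors, SFSPair

TE_TAXONOMY = pd.DataFrame(
    [
        ("Ty3", "Ty3", "retrotransposon"),
        ("Copia", "Copia", "retrotransposon"),
        ("LINE_L1", "L1", "retrotransposon"),
        ("MuDR", "MuDR", "DNA_transposon"),
        ("hAT", "hAT", "DNA_transposon"),
        ("Helitron", "Helitron", "DNA_transposon"),
        ("CACTA", "CACTA", "DNA_transposon"),
    ],
    columns=["family", "superfamily", "te_class"],
)


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic reciprocal-transplant study.

    Defaults emulate the study conditions: three populations grown at two
    field sites, ~30/10/3.5% CG/CHG/CHH methylation, 99.1% CG bisulfite
    conversion efficiency, theta = 0.005/site with a gamma DFE of shape 0.3
    and mean 2*N_e*s = 400, and an adaptive fixation fraction of 0.3.
    """

    seed: int = 0
    n_individuals_per_group: int = 6
    populations: tuple[str, ...] = ("J1", "J3", "GER")
    fields: tuple[str, ...] = ("low", "high")
    n_genes: int = 1000
    n_sites_per_class: dict = dc_field(
        default_factory=lambda: {"synonymous": 1_000_000, "nonsynonymous": 1_000_000}
    )
    theta_per_site: float = 0.005
    theta_multiplier: float = 2.76
    divergence_per_site: float = 0.05
    dfe_shape: float = 0.3
    dfe_mean: float = 400.0
    alpha_true: float = 0.3
    nb_dispersion: float = 0.1
    # expression effects on the log2 scale, methylation effects on the logit scale
    effect_sizes: dict = dc_field(
        default_factory=lambda: {
            "field": 2.0,
            "population": 2.0,
            "interaction": 2.0,
            "meth_field": 1.0,
            "meth_population": 1.0,
            "meth_interaction": 1.0,
        }
    )
    frac_affected: float = 0.05
    meth_levels: dict = dc_field(
        default_factory=lambda: {"CG": 0.30, "CHG": 0.10, "CHH": 0.035}
    )
    conversion_failure: float = 0.009
    n_cytosines_per_gene: int = 60
    depth_mean: float = 30.0
    depth_dispersion: float = 0.3
    expression_mean: float = 100.0
    posterior_concentration: float = 50.0
    te_frequency_spectrum: dict = dc_field(
        default_factory=lambda: {0.05: 0.40, 0.10: 0.20, 0.20: 0.15, 0.30: 0.10, 0.50: 0.10, 0.80: 0.05}
    )
    n_te_insertions: int = 500
    te_noise: float = 0.05
    te_coverage_mean: float = 20.0

    def __post_init__(self) -> None:
        for name, v in [("theta_per_site", self.theta_per_site)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, v in [
            ("conversion_failure", self.conversion_failure),
            ("frac_affected", self.frac_affected),
            *[(f"meth_levels[{k}]", p) for k, p in self.meth_levels.items()],
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.alpha_true < 1.0:
            raise ValueError("alpha_true must be in [0, 1)")
        if self.dfe_shape <= 0 or self.dfe_mean <= 0:
            raise ValueError("dfe_shape and dfe_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.fields) != 2:
            raise ValueError("exactly two field sites expected")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def design(self, n_individuals: int | None = None) -> pd.DataFrame:
        """Sample sheet for the factorial design (population x field)."""
        n = n_individuals or self.n_individuals_per_group
        rows = [
            {"sample": f"{p}_{f}_{i+1}", "population": p, "field": f}
            for p in self.populations
            for f in self.fields
            for i in range(n)
        ]
        return pd.DataFrame(rows)


@dataclass
class TrueDFE:
    """Ground-truth selection parameters behind a simulated SFS pair."""

    shape: float
    mean_2nes: float
    bins: np.ndarray
    alpha: float
    theta_s: float
    theta_n: float
    omega_na: float  # nonadaptive dN/dS relative to neutral


def simulate_sfs(
    config: SimConfig,
    n_haplotypes: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SFSPair, TrueDFE]:
    """Draw an unfolded SFS pair from the equilibrium PRF with gamma DFE.

    Synonymous bins are Poisson draws around the neutral Watterson
    expectations; nonsynonymous bins are Poisson around the gamma-DFE
    expectations at theta_N = theta_multiplier * theta_S.  Divergence counts
    are Poisson with dS neutral and dN carrying nonadaptive fixations
    (gamma-DFE fixation-probability reduction) inflated so that a fraction
    ``alpha_true`` of all nonsynonymous fixations is adaptive.
    """
    rng = rng or config.rng(1)
    n = n_haplotypes if n_haplotypes is not None else 2 * config.n_individuals_per_group
    if n % 2:
        raise ValueError("n must be even (diploid samples)")
    if n < 4:
        raise ValueError("n must be >= 4")
    l_s = float(config.n_sites_per_class["synonymous"])
    l_n = float(config.n_sites_per_class["nonsynonymous"])
    theta_s = config.theta_per_site
    theta_n = config.theta_multiplier * theta_s

    i = np.arange(1, n)
    e_syn = theta_s * l_s / i
    e_non = expected_sfs_gamma(n, theta_n, config.dfe_shape, config.dfe_mean, L=l_n)

    omega_na = mean_fixation_factor(config.dfe_shape, config.dfe_mean)
    d_rate = config.divergence_per_site
    e_ds = d_rate * l_s
    e_dn = d_rate * config.theta_multiplier * omega_na * l_n / (1.0 - config.alpha_true)

    sfs = SFSPair(
        n=n,
        folded=False,
        xi_s=rng.poisson(e_syn).astype(float),
        xi_n=rng.poisson(e_non).astype(float),
        l_s=l_s,
        l_n=l_n,
        d_s=float(rng.poisson(e_ds)),
        d_n=float(rng.poisson(e_dn)),
    )
    truth = TrueDFE(
        shape=config.dfe_shape,
        mean_2nes=config.dfe_mean,
        bins=dfe_bin_proportions(config.dfe_shape, config.dfe_mean),
        alpha=config.alpha_true,
        theta_s=theta_s,
        theta_n=theta_n,
        omega_na=omega_na,
    )
    return sfs, truth


def simulate_genotype_posteriors(
    config: SimConfig,
    n_sites: int = 200,
    freqs: np.ndarray | None = None,
    site_class: str = "synonymous",
    concentration: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypePosteriors, np.ndarray]:
    """True genotypes under HWE plus softened one-hot posterior triples.

    Posteriors are Dirichlet draws with concentration mass on the true
    genotype (alpha = concentration * onehot + 0.5); as the concentration
    grows the posteriors collapse onto the truth.  Returns the posterior
    container and the true genotype matrix (sites x individuals).
    """
    rng = rng or config.rng(2)
    conc = config.posterior_concentration if concentration is None else concentration
    if conc <= 0:
        raise ValueError("concentration must be positive")
    design = config.design()
    n_ind = len(design)
    n_hap = 2 * config.n_individuals_per_group * len(config.fields)
    if freqs is None:
        # neutral folded-frequency draw per population
        i = np.arange(1, n_hap)
        p_site = (1.0 / i) / np.sum(1.0 / i)
        freqs = np.empty((n_sites, len(config.populations)))
        for k in range(len(config.populations)):
            freqs[:, k] = rng.choice(i, size=n_sites, p=p_site) / n_hap
    pop_index = design["population"].map(
        {p: k for k, p in enumerate(config.populations)}
    ).to_numpy()
    site_freq = freqs[:, pop_index]  # (sites, individuals)
    true_geno = rng.binomial(2, site_freq)

    alpha = 0.5 + conc * (true_geno[:, :, None] == np.arange(3)[None, None, :])
    probs = rng.gamma(alpha)
    probs /= probs.sum(axis=2, keepdims=True)

    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 10,
            "ref": "A",
            "alt": "T",
            "site_class": site_class,
            "ancestral": "A",
        }
    )
    gp = GenotypePosteriors(sites=sites, individuals=design.rename(
        columns={"sample": "individual"})[["individual", "population"]], probs=probs)
    return gp, true_geno


def make_gene_annotation(config: SimConfig, gene_length: int = 2000,
                         spacer: int = 1000) -> pd.DataFrame:
    """Non-overlapping plus/minus-strand gene models on a single chromosome."""
    starts = 1 + np.arange(config.n_genes) * (gene_length + spacer)
    return pd.DataFrame(
        {
            "gene": [f"g{j+1:05d}" for j in range(config.n_genes)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + gene_length - 1,
            "strand": np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
        }
    )


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_methylation(
    config: SimConfig,
    genes: pd.DataFrame | None = None,
    affected: pd.DataFrame | None = None,
    chloroplast_sites: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bismark-style cytosine report for the factorial design.

    Per gene and individual, each cytosine's methylated-allele count is
    Binomial(2, p) with logit(p) = context baseline + any field/population/
    interaction effect assigned to the gene; reads then sample the allelic
    proportion with the bisulfite conversion-failure floor.  A chloroplast
    contig (naturally unmethylated) is emitted with methylation probability
    equal to the conversion failure only.

    Returns (table, genes, truth) where ``table`` has columns chrom, pos,
    strand, context, meth, total, individual and ``truth`` flags which genes
    carry which effects.
    """
    rng = rng or config.rng(3)
    genes = genes if genes is not None else make_gene_annotation(config)
    design = config.design()
    n_ind = len(design)
    n_genes = len(genes)
    n_cyt = config.n_cytosines_per_gene

    contexts = np.array(["CG", "CHG", "CHH", "CHH"])  # 1:1:2 default mix
    ctx = np.tile(contexts, int(np.ceil(n_cyt / 4)))[:n_cyt]
    ctx_all = np.tile(ctx, n_genes)

    if affected is None:
        eff_names = ("field", "population", "interaction")
        flags = {
            e: rng.random(n_genes) < config.frac_affected for e in eff_names
        }
        affected = pd.DataFrame({"gene": genes["gene"], **{
            f"dm_{e}": flags[e] for e in eff_names}})
    is_high = (design["field"] == config.fields[1]).to_numpy()
    is_ger = (design["population"] == config.populations[-1]).to_numpy()

    # meth_levels are the observed proportions (conversion failure included);
    # back out the allele-level baseline so measured levels match the target
    f0 = config.conversion_failure
    base = {
        k: logit(min(max((v - f0) / (1.0 - f0), 1e-6), 1.0 - 1e-6))
        for k, v in config.meth_levels.items()
    }
    eff = config.effect_sizes
    # per-gene, per-individual logit shift
    shift = np.zeros((n_genes, n_ind))
    shift += affected["dm_field"].to_numpy()[:, None] * eff["meth_field"] * is_high[None, :]
    shift += affected["dm_population"].to_numpy()[:, None] * eff["meth_population"] * is_ger[None, :]
    shift += (
        affected["dm_interaction"].to_numpy()[:, None]
        * eff["meth_interaction"]
        * (is_high & is_ger)[None, :]
    )

    gene_starts = genes["start"].to_numpy()
    gene_len = genes["end"].to_numpy() - gene_starts + 1
    offsets = np.sort(
        rng.integers(0, gene_len.min(), size=(n_genes, n_cyt)), axis=1
    )
    pos = (gene_starts[:, None] + offsets).ravel()
    strand = rng.choice(["+", "-"], size=n_genes * n_cyt)

    f = config.conversion_failure
    frames = []
    base_per_site = np.array([base[c] for c in ctx])  # (n_cyt,)
    for j, ind in enumerate(design["sample"]):
        p = expit(base_per_site[None, :] + shift[:, j][:, None])  # genes x cyt
        a = rng.binomial(2, p)  # methylated alleles
        depth = _nb_draw(rng, np.full(a.shape, config.depth_mean), config.depth_dispersion)
        p_read = a / 2.0 + (1.0 - a / 2.0) * f  # unconverted C reads as methylated
        meth = rng.binomial(depth, p_read)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "strand": strand,
                    "context": ctx_all,
                    "meth": meth.ravel(),
                    "total": depth.ravel(),
                    "individual": ind,
                }
            )
        )
    # chloroplast: unmethylated; apparent methylation = conversion failure
    cp_pos = np.arange(1, chloroplast_sites + 1) * 3
    cp_ctx = np.tile(contexts, int(np.ceil(chloroplast_sites / 4)))[:chloroplast_sites]
    for ind in design["sample"]:
        depth = _nb_draw(
            rng, np.full(chloroplast_sites, config.depth_mean), config.depth_dispersion
        )
        meth = rng.binomial(depth, f)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chloroplast",
                    "pos": cp_pos,
                    "strand": "+",
                    "context": cp_ctx,
                    "meth": meth,
                    "total": depth,
                    "individual": ind,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, genes, affected


def simulate_counts(
    config: SimConfig,
    affected: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts with factorial effects.

    Returns (counts, design, truth); truth flags which genes carry field /
    population / interaction effects (log2 fold changes from
    ``config.effect_sizes``).
    """
    rng = rng or config.rng(4)
    design = config.design()
    n_ind = len(design)
    n_genes = config.n_genes
    genes = [f"g{j+1:05d}" for j in range(n_genes)]

    if affected is None:
        eff_names = ("field", "population", "interaction")
        affected = pd.DataFrame({"gene": genes, **{
            f"de_{e}": rng.random(n_genes) < config.frac_affected for e in eff_names}})
    is_high = (design["field"] == config.fields[1]).to_numpy()
    is_ger = (design["population"] == config.populations[-1]).to_numpy()

    ln2 = np.log(2.0)
    eff = config.effect_sizes
    log_mu = np.log(rng.lognormal(np.log(config.expression_mean), 1.0, size=n_genes))[:, None]
    log_mu = log_mu + affected["de_field"].to_numpy()[:, None] * eff["field"] * ln2 * is_high[None, :]
    log_mu = log_mu + affected["de_population"].to_numpy()[:, None] * eff["population"] * ln2 * is_ger[None, :]
    log_mu = log_mu + (
        affected["de_interaction"].to_numpy()[:, None]
        * eff["interaction"] * ln2 * (is_high & is_ger)[None, :]
    )
    size_factors = rng.lognormal(0.0, 0.2, size=n_ind)
    mu = np.exp(log_mu) * size_factors[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=design["sample"].to_numpy())
    return counts_df, design, affected


def simulate_te_table(
    config: SimConfig,
    n_individuals: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TE insertion table with per-individual read-support proportions.

    Insertion population frequencies are drawn from the configured spectrum,
    genotypes are HWE within population, and read support is Gaussian noise
    around 0 / 0.5 / 1 (clipped to [0, 1]).  Returns the long-format table
    and the true genotype table.
    """
    rng = rng or config.rng(5)
    spec_f = np.array(list(config.te_frequency_spectrum.keys()), dtype=float)
    spec_p = np.array(list(config.te_frequency_spectrum.values()), dtype=float)
    if abs(spec_p.sum() - 1.0) > 1e-9:
        raise ValueError("te_frequency_spectrum must sum to 1")
    n_ins = config.n_te_insertions
    n_ind = n_individuals or config.n_individuals_per_group
    fam_w = np.array([0.35, 0.2, 0.1, 0.12, 0.1, 0.08, 0.05])
    fam_idx = rng.choice(len(TE_TAXONOMY), size=n_ins, p=fam_w / fam_w.sum())
    tax = TE_TAXONOMY.iloc[fam_idx].reset_index(drop=True)

    rows = []
    truth_rows = []
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=n_ins, replace=False))
    for k in range(n_ins):
        freqs = {
            p: float(rng.choice(spec_f, p=spec_p)) for p in config.populations
        }
        for p in config.populations:
            geno = rng.binomial(2, freqs[p], size=n_ind)
            cov = rng.poisson(config.te_coverage_mean, size=n_ind)
            support = np.clip(
                geno / 2.0 + rng.normal(0.0, config.te_noise, size=n_ind), 0.0, 1.0
            ) if config.te_noise > 0 else geno / 2.0
            for j in range(n_ind):
                rows.append(
                    (
                        "chr1", int(pos[k]), f"te{k+1:05d}", tax.at[k, "family"],
                        tax.at[k, "superfamily"], tax.at[k, "te_class"],
                        p, f"{p}_{j+1}", float(support[j]), int(cov[j]),
                    )
                )
                truth_rows.append(("chr1", int(pos[k]), f"te{k+1:05d}", p,
                                   f"{p}_{j+1}", int(geno[j])))
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "insertion", "family", "superfamily", "te_class",
            "population", "individual", "support", "coverage",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "insertion", "population", "individual", "genotype"],
    )
    return table, truth
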