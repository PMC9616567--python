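"""Methylation levels/profiles, conversion efficiency and TE utilities."""

import numpy as np
import pandas as pd
import pytest

from envsel.methylome_te import (
    conversion_efficiency,
    discretize_te_genotypes,
    distance_to_nearest,
    metagene_profile,
    methylation_level,
    subsample_te_individuals,
    te_composition,
    te_family_counts,
    te_presence_sfs,
)
from envsel.popgen import MonomorphicSpectrumError, tajimas_d
from envsel.simulate import SimConfig, simulate_methylation, simulate_te_table


def meth_table(records):
    return pd.DataFrame(
        records,
        columns=["chrom", "pos", "strand", "context", "meth", "total", "individual"],
    )


class TestMethylationLevel:
    def test_fully_methylated(self):
        t = meth_table([("chr1", 1, "+", "CG", 10, 10, "a"),
                        ("chr1", 2, "+", "CG", 5, 5, "a")])
        assert methylation_level(t) == 1.0

    def test_context_partition_is_exact(self):
        t = meth_table([("chr1", 1, "+", "CG", 10, 10, "a"),
                        ("chr1", 2, "+", "CHG", 0, 10, "a"),
                        ("chr1", 3, "+", "CHH", 5, 10, "a")])
        assert methylation_level(t, "CG") == 1.0
        assert methylation_level(t, "CHG") == 0.0
        assert methylation_level(t, "CH") == 0.25
        with pytest.raises(ValueError):
            methylation_level(t, "CNN")

    def test_generator_truth_recovered(self):
        cfg = SimConfig(seed=41, n_genes=200, n_individuals_per_group=2,
                        frac_affected=0.0, conversion_failure=0.0,
                        depth_mean=60.0)
        table, _, _ = simulate_methylation(cfg)
        nuc = table[table["chrom"] == "chr1"]
        assert methylation_level(nuc, "CG") == pytest.approx(0.30, abs=0.01)
        assert methylation_level(nuc, "CHG") == pytest.approx(0.10, abs=0.01)
        assert methylation_level(nuc, "CHH") == pytest.approx(0.035, abs=0.005)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            methylation_level(meth_table([]), "CG")


class TestConversionEfficiency:
    def test_zero_methylated_is_hundred_percent(self):
        t = meth_table([("chloroplast", 1, "+", "CG", 0, 100, "a")])
        assert conversion_efficiency(t)["CG"] == 1.0

    def test_printed_arithmetic(self):
        t = meth_table([("chloroplast", 1, "+", "CG", 9, 1000, "a")])
        assert conversion_efficiency(t)["CG"] == pytest.approx(0.991)

    def test_generator_truth(self):
        cfg = SimConfig(seed=42, n_genes=5, n_individuals_per_group=4,
                        conversion_failure=0.009, depth_mean=60.0)
        table, _, _ = simulate_methylation(cfg, chloroplast_sites=5000)
        eff = conversion_efficiency(table)
        assert eff["CG"] == pytest.approx(0.991, abs=0.002)

    def test_missing_chloroplast_rejected(self):
        with pytest.raises(ValueError):
            conversion_efficiency(meth_table([("chr1", 1, "+", "CG", 0, 5, "a")]))


class TestMetageneProfile:
    def _uniform_table(self, level=0.5, span=(1, 12000)):
        pos = np.arange(span[0], span[1], 7)
        return meth_table([
            ("chr1", int(p), "+", "CG", int(level * 10), 10, "a") for p in pos
        ])

    def test_uniform_methylation_flat_profile(self):
        feats = pd.DataFrame({"gene": ["g1"], "chrom": "chr1", "start": [4001],
                              "end": [8000], "strand": ["+"]})
        prof = metagene_profile(self._uniform_table(), feats)
        assert np.allclose(prof["level"].dropna(), 0.5)

    def test_minus_strand_profile_mirrored(self):
        # linear gradient across the body: minus-strand profile reverses it
        pos = np.arange(1001, 3001, 2)
        grad = (pos - 1001) / 2000
        t = meth_table([
            ("chr1", int(p), "+", "CG", int(round(g * 100)), 100, "a")
            for p, g in zip(pos, grad)
        ])
        plus = pd.DataFrame({"gene": ["g"], "chrom": "chr1", "start": [1001],
                             "end": [3000], "strand": ["+"]})
        minus = plus.assign(strand="-")
        p_plus = metagene_profile(t, plus, flank_bp=100)
        p_minus = metagene_profile(t, minus, flank_bp=100)
        body_p = p_plus[p_plus["segment"] == "body"]["level"].to_numpy()
        body_m = p_minus[p_minus["segment"] == "body"]["level"].to_numpy()
        assert np.allclose(body_p, body_m[::-1], atol=1e-6)

    def test_step_function_longhand(self):
        # two features with step patterns; longhand bin means
        t = meth_table(
            [("chr1", p, "+", "CG", 10 if p <= 1100 else 0, 10, "a")
             for p in range(1001, 1201, 10)]
            + [("chr1", p, "+", "CG", 0 if p <= 5100 else 10, 10, "a")
               for p in range(5001, 5201, 10)]
        )
        feats = pd.DataFrame({
            "gene": ["g1", "g2"], "chrom": "chr1",
            "start": [1001, 5001], "end": [1200, 5200], "strand": ["+", "+"],
        })
        prof = metagene_profile(t, feats, body_bins=2, flank_bp=100, flank_bins=2)
        body = prof[prof["segment"] == "body"].set_index("bin")
        # first half: g1 fully methylated (1.0), g2 unmethylated (0.0) -> 0.5
        assert body.loc[0, "level"] == pytest.approx(0.5)
        assert body.loc[1, "level"] == pytest.approx(0.5)

    def test_short_feature_skipped(self):
        feats = pd.DataFrame({"gene": ["tiny"], "chrom": "chr1", "start": [100],
                              "end": [105], "strand": ["+"]})
        prof = metagene_profile(self._uniform_table(), feats, body_bins=20)
        assert prof.attrs["skipped"] == 1

    def test_input_order_invariance(self):
        feats = pd.DataFrame({
            "gene": ["g1", "g2"], "chrom": "chr1",
            "start": [1001, 5001], "end": [3000, 7000], "strand": ["+", "+"],
        })
        t = self._uniform_table()
        a = metagene_profile(t, feats)
        b = metagene_profile(t, feats.iloc[::-1])
        assert np.allclose(a["level"].fillna(-1), b["level"].fillna(-1))


class TestTeFamilyCounts:
    def _assign(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "sample", "feature_kind",
                                           "family"])

    def test_same_family_multimapper_counted_once(self):
        a = self._assign([("r1", "s1", "TE", "A"), ("r1", "s1", "TE", "A")])
        out = te_family_counts(a)
        assert out.loc["A", "s1"] == 1

    def test_multi_family_read_excluded(self):
        a = self._assign([("r1", "s1", "TE", "A"), ("r1", "s1", "TE", "B"),
                          ("r2", "s1", "TE", "B")])
        out = te_family_counts(a)
        assert "A" not in out.index
        assert out.loc["B", "s1"] == 1

    def test_gene_overlap_excluded(self):
        a = self._assign([("r1", "s1", "gene", None), ("r1", "s1", "TE", "A"),
                          ("r2", "s1", "TE", "A")])
        out = te_family_counts(a)
        assert out.loc["A", "s1"] == 1

    def test_each_read_counted_at_most_once(self, rng):
        rows = []
        for r in range(50):
            k = rng.integers(1, 4)
            fams = rng.choice(["A", "B", "C"], size=k)
            for f in fams:
                rows.append((f"r{r}", "s1", "TE", f))
        out = te_family_counts(self._assign(rows))
        assert out.to_numpy().sum() <= 50

    def test_unknown_family_rejected(self):
        a = self._assign([("r1", "s1", "TE", "Zeta")])
        with pytest.raises(ValueError):
            te_family_counts(a, families=["A", "B"])


class TestDiscretizeTeGenotypes:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["insertion", "individual", "support",
                                           "coverage"])

    @pytest.mark.parametrize("support, coverage, expected", [
        (0.9, 10, 2.0),
        (0.5, 10, 1.0),
        (0.1, 10, 0.0),
        (0.85, 10, 1.0),  # printed boundary belongs to the heterozygote
        (0.15, 10, 1.0),
        (0.10, 5, np.nan),  # below 6x coverage -> missing
    ])
    def test_threshold_table(self, support, coverage, expected):
        out = discretize_te_genotypes(self._table([("t1", "a", support, coverage)]))
        v = out.loc["t1", "a"]
        assert (np.isnan(v) and np.isnan(expected)) or v == expected

    def test_pure_threshold_idempotent(self, rng):
        t = self._table([(f"t{i}", "a", float(s), 10)
                         for i, s in enumerate(rng.random(50))])
        a = discretize_te_genotypes(t)
        b = discretize_te_genotypes(t.iloc[::-1])
        assert a.sort_index().equals(b.sort_index())

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValueError):
            discretize_te_genotypes(self._table([("t1", "a", 1.2, 10)]))


class TestTeComposition:
    def _taxonomy(self, classes):
        return pd.DataFrame({
            "insertion": list(classes),
            "family": "f",
            "superfamily": "s",
            "te_class": list(classes.values()),
        })

    def test_single_class(self):
        geno = pd.DataFrame({"a": [2.0, 1.0]}, index=["t1", "t2"])
        tax = self._taxonomy({"t1": "retrotransposon", "t2": "retrotransposon"})
        comp = te_composition(geno, tax, n_bootstrap=50, seed=0)
        assert comp.loc["retrotransposon", "proportion"] == 1.0

    def test_equal_copies_half_half(self):
        geno = pd.DataFrame({"a": [2.0, 2.0]}, index=["t1", "t2"])
        tax = self._taxonomy({"t1": "retrotransposon", "t2": "DNA_transposon"})
        comp = te_composition(geno, tax, n_bootstrap=50, seed=0)
        assert np.allclose(comp["proportion"], 0.5)

    def test_longhand_dosage_tally(self, rng):
        ins = [f"t{i}" for i in range(10)]
        geno = pd.DataFrame(
            rng.integers(0, 3, size=(10, 4)).astype(float),
            index=ins, columns=list("abcd"),
        )
        classes = dict(zip(ins, rng.choice(["retrotransposon", "DNA_transposon"],
                                           size=10)))
        comp = te_composition(geno, self._taxonomy(classes), n_bootstrap=10, seed=0)
        dose = geno.sum(axis=1)
        retro = sum(dose[i] for i in ins if classes[i] == "retrotransposon")
        assert comp.loc["retrotransposon", "proportion"] == pytest.approx(
            retro / dose.sum())


class TestDistance:
    def _feats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_overlap_is_zero(self):
        a = self._feats([("chr1", 100, 200)])
        b = self._feats([("chr1", 150, 300)])
        assert distance_to_nearest(a, b).iloc[0] == 0.0

    def test_gap_convention(self):
        # gene ends at 100, TE starts at 150 (1-based inclusive): 49 bases between
        a = self._feats([("chr1", 50, 100)])
        b = self._feats([("chr1", 150, 200)])
        assert distance_to_nearest(a, b).iloc[0] == 49.0

    def test_missing_chromosome_is_nan(self):
        a = self._feats([("chr2", 50, 100)])
        b = self._feats([("chr1", 150, 200)])
        assert np.isnan(distance_to_nearest(a, b).iloc[0])

    def test_empty_b_rejected(self):
        with pytest.raises(ValueError):
            distance_to_nearest(self._feats([("chr1", 1, 2)]), self._feats([]))


class TestTePresenceSfs:
    def test_singleton_skew_gives_lower_tajima_d(self):
        skew = SimConfig(seed=51, n_te_insertions=300, n_individuals_per_group=9,
                         te_frequency_spectrum={0.05: 0.9, 0.5: 0.1})
        unif = SimConfig(seed=51, n_te_insertions=300, n_individuals_per_group=9,
                         te_frequency_spectrum={0.1: 0.25, 0.3: 0.25,
                                                0.5: 0.25, 0.7: 0.25})
        ds = {}
        for name, cfg in (("skew", skew), ("unif", unif)):
            table, _ = simulate_te_table(cfg)
            geno = discretize_te_genotypes(table)
            inds = sorted(table[table["population"] == "J1"]["individual"].unique())
            xi, n = te_presence_sfs(geno, inds)
            ds[name] = tajimas_d(xi, n)
        assert ds["skew"] < ds["unif"]

    def test_all_fixed_flagged_undefined(self):
        cfg = SimConfig(seed=52, n_te_insertions=50, n_individuals_per_group=4,
                        te_noise=0.0, te_frequency_spectrum={1.0: 1.0})
        table, _ = simulate_te_table(cfg)
        geno = discretize_te_genotypes(table)
        inds = sorted(table[table["population"] == "J1"]["individual"].unique())
        xi, n = te_presence_sfs(geno, inds)
        with pytest.raises(MonomorphicSpectrumError):
            tajimas_d(xi, n)

    def test_subsampling_equalizes_individuals(self):
        cfg = SimConfig(seed=53, n_te_insertions=20, n_individuals_per_group=9)
        table, _ = simulate_te_table(cfg)
        sub = subsample_te_individuals(table, 5, seed=1)
        per_pop = sub.groupby("population")["individual"].nunique()
        assert (per_pop == 5).all()
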