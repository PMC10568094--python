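"""Clumping, thresholding, score assembly and sample scoring."""

import numpy as np
import pandas as pd
import pytest

from ibdprofiler.cohort_io import (
    GenotypeMatrix,
    ScoreModel,
    SummaryStats,
    VariantRecord,
)
from ibdprofiler.prs_builder import (
    ClumpConfig,
    GeneRegion,
    MhcClumpConfig,
    build_score_model,
    clump,
    clump_mhc,
    locus_score_model,
    score_samples,
)
from ibdprofiler.structure_qc import dosage_r2

from conftest import toy_genotypes


def make_stats(genotypes, p_values, betas=None):
    v = genotypes.variants
    n = len(v)
    betas = np.full(n, 0.1) if betas is None else np.asarray(betas, dtype=float)
    df = v.copy()
    df["beta"] = betas
    df["se"] = 0.05
    df["p_value"] = np.asarray(p_values, dtype=float)
    df["maf"] = genotypes.maf()
    df["n_cases"] = df["n_controls"] = 100
    return SummaryStats(df)


def clump_oracle(stats, genotypes, config):
    """Exhaustive reference implementation of the greedy clumping rule."""
    df = stats.valid()
    df = df[df["p_value"] <= config.p_threshold]
    order = df.sort_values(["p_value", "position_bp", "id"], kind="mergesort")
    unassigned = list(order["id"])
    info = order.set_index("id")
    result = []
    while unassigned:
        index = unassigned.pop(0)
        members = []
        for other in list(unassigned):
            same_chrom = info.loc[other, "chromosome"] == info.loc[index, "chromosome"]
            close = abs(
                int(info.loc[other, "position_bp"])
                - int(info.loc[index, "position_bp"])
            ) <= config.radius_bp
            if same_chrom and close:
                r2 = dosage_r2(
                    genotypes.dosages[:, genotypes.variant_index(index)],
                    genotypes.dosages[:, genotypes.variant_index(other)],
                )
                if r2 > config.r2_threshold:
                    members.append(other)
                    unassigned.remove(other)
        result.append((index, frozenset(members)))
    return result


def as_comparable(clumpset):
    return [(c.index_id, frozenset(c.member_ids)) for c in clumpset.clumps]


class TestClump:
    def test_uncorrelated_all_indices(self):
        g = toy_genotypes(400, 10, seed=0)
        stats = make_stats(g, np.linspace(1e-6, 0.05, 10))
        cs = clump(stats, g, ClumpConfig(p_threshold=0.1))
        assert len(cs) == 10
        assert all(not c.member_ids for c in cs.clumps)

    def test_correlated_pair_single_clump(self):
        g = toy_genotypes(400, 2, seed=1, spacing=10_000)
        g.dosages[:, 1] = np.clip(
            g.dosages[:, 0] + (np.arange(400) % 10 == 0), 0, 2
        )
        stats = make_stats(g, [1e-8, 1e-4])
        cs = clump(stats, g, ClumpConfig(p_threshold=0.1))
        assert len(cs) == 1
        assert cs.clumps[0].index_id == "rs0"
        assert cs.clumps[0].member_ids == ("rs1",)

    def test_radius_respected(self):
        g = toy_genotypes(400, 2, seed=2, spacing=400_000)
        g.dosages[:, 1] = g.dosages[:, 0]
        stats = make_stats(g, [1e-8, 1e-4])
        cs = clump(stats, g, ClumpConfig(radius_bp=250_000, p_threshold=0.1))
        assert len(cs) == 2  # perfect LD but outside the radius

    def test_p_threshold_applied_before_clumping(self):
        g = toy_genotypes(400, 3, seed=3)
        stats = make_stats(g, [1e-8, 0.5, 1e-4])
        cs = clump(stats, g, ClumpConfig(p_threshold=0.01))
        assert sorted(cs.index_ids()) == ["rs0", "rs2"]

    def test_missing_ld_variant_errors(self):
        g = toy_genotypes(100, 2, seed=4)
        stats = make_stats(g, [0.01, 0.01])
        with pytest.raises(KeyError, match="rs"):
            clump(stats, g.take_variants(np.array([0])), ClumpConfig())

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n, m = 80, rng.integers(10, 50)
        base = rng.binomial(2, rng.uniform(0.1, 0.5, 8), size=(n, 8)).astype(float)
        cols = [
            np.clip(base[:, rng.integers(8)] + rng.binomial(1, 0.3, n), 0, 2)
            for _ in range(m)
        ]
        g = GenotypeMatrix(
            np.column_stack(cols), [f"s{i}" for i in range(n)],
            [VariantRecord(f"v{j:02d}", "1", 1 + j * rng.integers(1000, 100_000), "A", "G")
             for j in range(m)],
        )
        pvals = 10 ** rng.uniform(-9, 0, m)
        stats = make_stats(g, pvals)
        cfg = ClumpConfig(
            radius_bp=int(rng.integers(50_000, 2_000_000)),
            r2_threshold=float(rng.uniform(0.05, 0.8)),
            p_threshold=float(rng.uniform(0.01, 1.0)),
        )
        assert as_comparable(clump(stats, g, cfg)) == clump_oracle(stats, g, cfg)

    def test_invariants_on_output(self):
        g = toy_genotypes(200, 30, seed=5, spacing=50_000)
        stats = make_stats(g, 10 ** np.random.default_rng(6).uniform(-8, 0, 30))
        cfg = ClumpConfig(p_threshold=0.5)
        cs = clump(stats, g, cfg)
        info = stats.table.set_index("id")
        seen = set()
        for c in cs.clumps:
            assert c.index_id not in seen
            seen.add(c.index_id)
            for m in c.member_ids:
                assert m not in seen
                seen.add(m)
                assert info.loc[m, "p_value"] >= c.index_p
                assert abs(
                    info.loc[m, "position_bp"] - info.loc[c.index_id, "position_bp"]
                ) <= cfg.radius_bp


class TestClumpMhc:
    def _mhc_genotypes(self, n=400, m=9, r=0.28, seed=7):
        """Mutually weakly-correlated variants inside the MHC region."""
        rng = np.random.default_rng(seed)
        shared = rng.binomial(2, 0.4, n).astype(float)
        cols = [
            np.where(rng.random(n) < r, shared, rng.binomial(2, 0.4, n))
            for _ in range(m)
        ]
        variants = [
            VariantRecord(f"m{j}", "6", 26_000_000 + j * 200_000, "A", "G")
            for j in range(m)
        ]
        return GenotypeMatrix(
            np.column_stack(cols), [f"s{i}" for i in range(n)], variants
        )

    def test_single_variant_region(self):
        g = self._mhc_genotypes(m=1)
        stats = make_stats(g, [1e-6])
        cs = clump_mhc(stats, g, MhcClumpConfig())
        assert len(cs) == 1

    def test_threshold_straddling_merges_on_later_passes(self):
        """Pairwise r^2 between the first-pass threshold (0.1) and the
        later threshold (0.05) keeps variants apart on pass 1 and merges
        them on passes 2-3."""
        g = self._mhc_genotypes(n=2000, m=3, r=0.56, seed=8)
        r2s = [dosage_r2(g.dosages[:, a], g.dosages[:, b])
               for a, b in ((0, 1), (0, 2), (1, 2))]
        assert all(0.05 < r2 < 0.1 for r2 in r2s), r2s
        stats = make_stats(g, [1e-8, 1e-7, 1e-6])
        pass1 = clump_mhc(stats, g, MhcClumpConfig(r2_schedule=(0.1,)))
        assert len(pass1) == 3
        full = clump_mhc(stats, g, MhcClumpConfig(r2_schedule=(0.1, 0.05, 0.05)))
        assert len(full) == 1
        assert full.clumps[0].index_id == "m0"
        assert sorted(full.clumps[0].member_ids) == ["m1", "m2"]

    def test_pass_counts_match_oracle_composition(self):
        """Each pass equals a fresh greedy clump of the surviving indices
        at the scheduled r^2 (composition semantics)."""
        g = self._mhc_genotypes(m=9, r=0.35, seed=9)
        pvals = 10 ** np.random.default_rng(10).uniform(-9, -1, 9)
        stats = make_stats(g, pvals)
        cfg = MhcClumpConfig(r2_schedule=(0.1, 0.05, 0.05), p_threshold=1.0)
        expected = stats
        base = ClumpConfig(radius_bp=cfg.radius_bp, r2_threshold=0.1, p_threshold=1.0)
        survivors = clump_oracle(expected, g, base)
        for r2 in (0.05, 0.05):
            ids = [i for i, _ in survivors]
            sub = stats.restrict(ids)
            survivors = clump_oracle(
                sub, g, ClumpConfig(radius_bp=cfg.radius_bp, r2_threshold=r2,
                                    p_threshold=1.0)
            )
        cs = clump_mhc(stats, g, cfg)
        assert sorted(cs.index_ids()) == sorted(i for i, _ in survivors)


class TestBuildScoreModel:
    def test_empty_clumpsets(self):
        g = toy_genotypes(100, 3, seed=11)
        stats = make_stats(g, [0.5, 0.5, 0.5])
        model = build_score_model([], stats, p_threshold=0.1)
        assert len(model) == 0

    def test_weights_are_betas(self):
        g = toy_genotypes(200, 4, seed=12)
        betas = [0.4, -0.2, 0.1, 0.05]
        stats = make_stats(g, [1e-6, 1e-5, 1e-4, 0.5], betas=betas)
        cs = clump(stats, g, ClumpConfig(p_threshold=0.1))
        model = build_score_model([cs], stats, p_threshold=0.01)
        got = model.entries.set_index("id")["weight"]
        assert got.to_dict() == {"rs0": 0.4, "rs1": -0.2, "rs2": 0.1}

    def test_override_replaces_region_entries(self):
        g = toy_genotypes(200, 4, seed=13, spacing=100_000)
        stats = make_stats(g, [1e-6, 1e-6, 1e-6, 1e-6])
        cs = clump(stats, g, ClumpConfig(p_threshold=0.1))
        region = GeneRegion("NOD2", "1", 1, 120_000, flank_bp=0)  # rs0, rs1
        fine = pd.DataFrame(
            {"id": [f"fm{i}" for i in range(10)],
             "effect_allele": "A",
             "weight": np.linspace(0.1, 1.0, 10)}
        )
        model = build_score_model([cs], stats, p_threshold=0.1,
                                  overrides=[(region, fine)])
        ids = set(model.entries["id"])
        assert {f"fm{i}" for i in range(10)} <= ids
        assert "rs0" not in ids and "rs1" not in ids
        assert {model.region_tags[f"fm{i}"] for i in range(10)} == {"NOD2"}

    def test_entry_count_monotone_in_threshold(self):
        g = toy_genotypes(300, 40, seed=14, spacing=300_000)
        pv = 10 ** np.random.default_rng(15).uniform(-6, 0, 40)
        stats = make_stats(g, pv)
        counts = []
        for thr in (0.1, 0.01, 0.001):
            cs = clump(stats, g, ClumpConfig(p_threshold=thr))
            counts.append(len(build_score_model([cs], stats, p_threshold=thr)))
        assert counts[0] >= counts[1] >= counts[2]


class TestScoreSamples:
    def _model(self, entries):
        return ScoreModel(pd.DataFrame(entries))

    def test_zero_weights(self):
        g = toy_genotypes(50, 3, seed=16)
        model = self._model(
            {"id": ["rs0", "rs1"], "effect_allele": ["A", "A"],
             "other_allele": ["G", "G"], "weight": [0.0, 0.0]}
        )
        np.testing.assert_array_equal(score_samples(g, model), np.zeros(50))

    def test_single_entry_arithmetic(self):
        g = toy_genotypes(10, 1, seed=17)
        g.dosages[:, 0] = 2.0
        model = self._model(
            {"id": ["rs0"], "effect_allele": ["A"], "other_allele": ["G"],
             "weight": [np.log(2)]}
        )
        np.testing.assert_allclose(
            score_samples(g, model), 2 * np.log(2) * np.ones(10)
        )

    def test_swapped_alleles_reconciled(self):
        g = toy_genotypes(80, 2, seed=18)
        straight = self._model(
            {"id": ["rs0", "rs1"], "effect_allele": ["A", "A"],
             "other_allele": ["G", "G"], "weight": [0.3, -0.2]}
        )
        swapped = self._model(
            {"id": ["rs0", "rs1"], "effect_allele": ["G", "A"],
             "other_allele": ["A", "G"], "weight": [-0.3, -0.2]}
        )
        s1 = score_samples(g, straight)
        s2 = score_samples(g, swapped)
        # hand-flipped model: w*(2-d) shifts scores by a constant 2w
        np.testing.assert_allclose(s2 - s1, (-0.3) * 2 * np.ones(80), atol=1e-12)

    def test_allele_mismatch_errors(self):
        g = toy_genotypes(20, 1, seed=19)
        model = self._model(
            {"id": ["rs0"], "effect_allele": ["C"], "other_allele": ["T"],
             "weight": [0.1]}
        )
        with pytest.raises(ValueError, match="mismatch"):
            score_samples(g, model)

    def test_missing_dosage_mean_imputed(self):
        g = toy_genotypes(100, 1, seed=20)
        g.dosages[0, 0] = np.nan
        model = self._model(
            {"id": ["rs0"], "effect_allele": ["A"], "other_allele": ["G"],
             "weight": [1.0]}
        )
        s = score_samples(g, model)
        assert s[0] == pytest.approx(np.nanmean(g.dosages[:, 0]))

    def test_linearity_in_weights(self):
        g = toy_genotypes(60, 3, seed=21)
        w = np.array([0.2, -0.4, 0.1])
        m1 = self._model(
            {"id": ["rs0", "rs1", "rs2"], "effect_allele": ["A"] * 3,
             "other_allele": ["G"] * 3, "weight": w}
        )
        m3 = self._model(
            {"id": ["rs0", "rs1", "rs2"], "effect_allele": ["A"] * 3,
             "other_allele": ["G"] * 3, "weight": 3 * w}
        )
        np.testing.assert_allclose(
            score_samples(g, m3), 3 * score_samples(g, m1), atol=1e-12
        )

    def test_model_variant_absent_errors(self):
        g = toy_genotypes(20, 1, seed=22)
        model = self._model(
            {"id": ["rsX"], "effect_allele": ["A"], "other_allele": ["G"],
             "weight": [0.1]}
        )
        with pytest.raises(KeyError, match="rsX"):
            score_samples(g, model)


class TestLocusScoreModel:
    def test_empty_region_warns(self):
        g = toy_genotypes(100, 3, seed=23)
        stats = make_stats(g, [0.01] * 3)
        region = GeneRegion("EMPTY", "9", 1, 1000, flank_bp=0)
        with pytest.warns(UserWarning, match="no variants"):
            model = locus_score_model(stats, g, region)
        assert len(model) == 0

    def test_whole_chromosome_equals_full_build(self):
        g = toy_genotypes(200, 10, seed=24, spacing=200_000)
        pv = 10 ** np.random.default_rng(25).uniform(-6, 0, 10)
        stats = make_stats(g, pv)
        region = GeneRegion("ALL1", "1", 1, 10_000_000, flank_bp=0)
        via_region = locus_score_model(stats, g, region,
                                       ClumpConfig(p_threshold=0.1))
        cs = clump(stats, g, ClumpConfig(p_threshold=0.1))
        direct = build_score_model([cs], stats, p_threshold=0.1)
        pd.testing.assert_frame_equal(
            via_region.entries.sort_values("id").reset_index(drop=True),
            direct.entries.sort_values("id").reset_index(drop=True),
        )
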