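"""OTU-table analyses: Kruskal-Wallis (exact and asymptotic), robustness and
enrichment calls, Bray-Curtis, PCoA, ANOSIM — each checked against an
independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from holopheno.design import ExperimentDesign
from holopheno.microbiome import (
    OtuTable,
    anosim,
    bray_curtis,
    classify_enriched_depleted,
    classify_robust_colonizers,
    kw_test,
    pcoa,
    relative_abundance,
    shifted_otu_sets,
)


def toy_table(counts, syncom_flags, inoculated):
    """Minimal OtuTable: counts is OTUs x samples array."""
    counts = np.asarray(counts)
    otus = [f"O{i}" for i in range(counts.shape[0])]
    samples = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "hybrid": "H1",
            "inoculated": inoculated,
            "regime": "WW",
            "replicate": range(1, counts.shape[1] + 1),
        },
        index=pd.Index(samples, name="sample"),
    )
    flags = pd.Series(syncom_flags, index=otus)
    return OtuTable(
        counts=pd.DataFrame(counts, index=otus, columns=samples),
        taxonomy=pd.Series("t", index=otus),
        syncom=flags,
        isolate=pd.Series(["iso" if f else "" for f in syncom_flags], index=otus),
        sample_meta=meta,
    )


class TestRelativeAbundance:
    def test_simple_proportions(self):
        t = toy_table([[30], [70]], [False, False], [0])
        rel = relative_abundance(t)
        np.testing.assert_allclose(rel["s0"], [0.3, 0.7])

    def test_single_otu_sample(self):
        t = toy_table([[5], [0]], [False, False], [0])
        assert relative_abundance(t)["s0"].iloc[0] == 1.0

    def test_zero_sample_rejected(self):
        t = toy_table([[0, 1], [0, 1]], [False, False], [0, 1])
        with pytest.raises(ValueError, match="zero total"):
            relative_abundance(t)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kw_test([1, 2, 3], [1, 2, 3], mode="chi2")
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_constant_pooled_convention(self):
        assert kw_test([5, 5], [5, 5]) == (0.0, 1.0)

    def test_complete_separation_tie_free(self):
        # ranks 5-8 vs 1-4: H = 12/72 * (4*2^2 + 4*2^2) = 16/3
        h, p = kw_test([10, 11, 12, 9], [0.0, 0.02, 0.1, 0.05], mode="exact")
        assert h == pytest.approx(5.333, abs=1e-3)
        assert p == pytest.approx(0.0286, abs=1e-4)  # 2 / C(8,4)

    def test_tie_correction_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, 6).astype(float)
            b = rng.integers(0, 5, 6).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            h, p = kw_test(a, b, mode="chi2")
            h_ref, p_ref = stats.kruskal(a, b)
            assert h == pytest.approx(h_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Independent oracle: enumerate every C(n, n_a) labeling with
        scipy's H statistic and count the upper tail."""
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(1.0, size=4)
            h_obs, p_exact = kw_test(a, b, mode="exact")
            pooled = np.concatenate([a, b])
            hs = []
            for idx in itertools.combinations(range(8), 4):
                g1 = pooled[list(idx)]
                g2 = pooled[[i for i in range(8) if i not in idx]]
                hs.append(stats.kruskal(g1, g2).statistic)
            oracle = np.mean([h >= h_obs - 1e-9 for h in hs])
            assert p_exact == pytest.approx(oracle, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kw_test([1.0], [2.0, 3.0])


class TestRobustColonizers:
    def test_spiked_otu_called_robust(self):
        counts = np.array(
            [[500, 520, 480, 510, 50, 55, 45, 60],  # SynCom, 10x in inoculated
             [5000] * 8]
        )
        t = toy_table(counts, [True, False], [1, 1, 1, 1, 0, 0, 0, 0])
        calls = classify_robust_colonizers(t, mode="exact")
        assert calls["robust"].all()
        assert calls["p_value"].iloc[0] == pytest.approx(0.0286, abs=1e-4)

    def test_absent_otu_not_robust(self):
        counts = np.array([[0] * 8, [5000] * 8])
        t = toy_table(counts, [True, False], [1, 1, 1, 1, 0, 0, 0, 0])
        calls = classify_robust_colonizers(t, mode="exact")
        assert not calls["robust"].any()

    def test_direction_rule_blocks_displaced_taxa(self):
        # significantly HIGHER in uninoculated: not a robust colonizer
        counts = np.array(
            [[50, 55, 45, 60, 500, 520, 480, 510],
             [5000] * 8]
        )
        t = toy_table(counts, [True, False], [1, 1, 1, 1, 0, 0, 0, 0])
        calls = classify_robust_colonizers(t, mode="exact")
        assert (calls["p_value"] < 0.05).iloc[0]
        assert not calls["robust"].iloc[0]

    def test_missing_arm_untestable(self):
        counts = np.array([[10, 20, 30, 40], [1, 2, 3, 4]])
        t = toy_table(counts, [True, False], [1, 1, 1, 1])
        calls = classify_robust_colonizers(t, mode="exact")
        assert not calls["testable"].any()
        assert not calls["robust"].any()


class TestEnrichedDepleted:
    def test_partition_and_syncom_exclusion(self, small_design, sim):
        table = sim["otu"]
        calls = classify_enriched_depleted(table)
        assert set(calls["call"]) <= {"enriched", "depleted", "unchanged"}
        assert calls.groupby(["otu_id", "regime"]).size().eq(1).all()
        assert not calls["otu_id"].isin(table.syncom_otus).any()

    def test_shifted_residents_called_with_direction(self, sim):
        table = sim["otu"]
        calls = classify_enriched_depleted(table)
        up = [f"RES{i + 1:04d}" for i in range(50, 60)]
        down = [f"RES{i + 1:04d}" for i in range(60, 70)]
        sub = calls.set_index(["otu_id", "regime"])
        up_calls = [sub.loc[(o, r), "call"] for o in up for r in ("WW", "DS")]
        down_calls = [sub.loc[(o, r), "call"] for o in down for r in ("WW", "DS")]
        assert np.mean([c == "enriched" for c in up_calls]) >= 0.8
        assert np.mean([c == "depleted" for c in down_calls]) >= 0.8

    def test_regime_set_combinations(self, sim):
        calls = classify_enriched_depleted(sim["otu"])
        sets = shifted_otu_sets(calls)
        assert sets["intersection"] <= sets["union"]
        for regime_set in sets["per_regime"].values():
            assert sets["intersection"] <= regime_set <= sets["union"]


class TestBrayCurtis:
    def test_identical_samples(self):
        d = bray_curtis(np.array([[2, 2], [3, 3]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports(self):
        d = bray_curtis(np.array([[2, 0], [0, 3]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_computed_value(self):
        d = bray_curtis(np.array([[2, 4], [2, 0], [0, 0]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)  # 1 - 2*2/8

    def test_matches_scipy_oracle(self, rng):
        x = rng.integers(0, 50, size=(12, 6)).astype(float)
        x[0, :] += 1  # no all-zero samples
        d = bray_curtis(x)
        for i in range(6):
            for j in range(6):
                assert d.iloc[i, j] == pytest.approx(
                    0.0 if i == j else scipy_braycurtis(x[:, i], x[:, j]), abs=1e-12
                )

    def test_joint_rescaling_invariance(self, rng):
        x = rng.random((8, 4)) + 0.1
        np.testing.assert_allclose(bray_curtis(x), bray_curtis(7.7 * x), atol=1e-12)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[0, 0, 1], [0, 0, 2]]))


class TestPcoa:
    def test_two_samples_closed_form(self):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(d, k=1)
        np.testing.assert_allclose(
            np.abs(res.coordinates["PC1"]), 0.4, atol=1e-12
        )

    def test_three_equidistant_samples(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(pd.DataFrame(d), k=2)
        ev = res.eigenvalues
        assert ev[0] == pytest.approx(ev[1], rel=1e-9)
        assert ev[0] > 0

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(pd.DataFrame(d), k=3)
        coords = res.coordinates.to_numpy()
        d_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d_hat, d, atol=1e-8)

    def test_truncation_warns(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            pcoa(d, k=5)

    def test_matches_skbio_oracle(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.integers(1, 50, size=(10, 8)).astype(float)
        d = bray_curtis(x)
        mine = pcoa(d, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        np.testing.assert_allclose(
            mine.eigenvalues[:2], ref.eigvals.to_numpy()[:2], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.iloc[:, :2].to_numpy()),
            atol=1e-6,
        )


def separated_distance(n_per=3, gap=10.0):
    """Two tight clusters far apart: every between > every within."""
    rng = np.random.default_rng(0)
    pts = np.concatenate([rng.random(n_per), gap + rng.random(n_per)])
    d = np.abs(pts[:, None] - pts[None, :])
    labels = np.array([0] * n_per + [1] * n_per)
    return pd.DataFrame(d), labels


class TestAnosim:
    def test_full_separation_gives_r_one(self):
        d, labels = separated_distance()
        res = anosim(d, labels, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self, rng):
        d = pd.DataFrame(np.abs(rng.normal(size=(10, 10))))
        d = (d + d.T) / 2
        np.fill_diagonal(d.values, 0.0)
        rs = []
        for s in range(100):
            labels = rng.permutation([0] * 5 + [1] * 5)
            rs.append(anosim(d, labels, n_perm=9, seed=s).r)
        assert abs(np.mean(rs)) < 0.05

    def test_exhaustive_matches_enumeration_oracle(self):
        """Brute force: recompute R for all 6! label orders directly from the
        rank definition and compare tail fractions."""
        rng = np.random.default_rng(4)
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = anosim(pd.DataFrame(d), labels, exhaustive=True)

        iu = np.triu_indices(6, 1)
        ranks = stats.rankdata(d[iu])
        m = ranks.size

        def r_stat(lab):
            between = lab[iu[0]] != lab[iu[1]]
            return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)

        r_obs = r_stat(labels)
        rs = {perm: r_stat(np.array(perm)) for perm in itertools.permutations(labels)}
        p_oracle = np.mean([r >= r_obs - 1e-12 for r in rs.values()])
        assert res.r == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_skbio_r(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.integers(1, 40, size=(15, 10)).astype(float)
        d = bray_curtis(x)
        labels = np.array([0, 1] * 5)
        mine = anosim(d, labels, n_perm=99, seed=1)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=[str(g) for g in labels],
            permutations=0,
        )
        assert mine.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_seeded_determinism(self):
        d, labels = separated_distance(n_per=4)
        a = anosim(d, labels, n_perm=199, seed=42)
        b = anosim(d, labels, n_perm=199, seed=42)
        assert a == b

    def test_singleton_group_rejected(self):
        d, _ = separated_distance()
        with pytest.raises(ValueError, match="at least two samples"):
            anosim(d, [0, 0, 0, 0, 0, 1], n_perm=9)

    def test_design_integration(self, sim):
        table = sim["otu"]
        rel = relative_abundance(table)
        d = bray_curtis(rel)
        groups = table.sample_meta.loc[list(d.index), "inoculated"].to_numpy()
        res = anosim(d, groups, n_perm=99, seed=0)
        assert res.r > 0.3 and res.p_value <= 0.05
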