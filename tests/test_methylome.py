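"""Density statistics, prevalence, partial correlation, rarefaction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from phameth.methylome import (
    CDS,
    MethylationSite,
    cds_summary,
    coding_mask,
    compute_rpkm,
    functional_rates,
    methylation_density,
    partial_pearson,
    prevalence,
    rarefaction,
    region_split,
    residualize,
)


def site(pos, strand="+", t="m6A", genome="g"):
    return MethylationSite(genome, pos, strand, t)


class TestDensity:
    def test_hand_counted_example(self):
        # "AACC": two forward A, zero forward T -> denominator 2
        assert methylation_density([site(0)], "AACC", "m6A") == 0.5

    def test_no_sites_zero(self):
        assert methylation_density([], "ACGT", "m6A") == 0.0

    def test_full_methylation_reaches_one(self):
        seq = "AATT"
        sites = [site(0), site(1), site(2, "-"), site(3, "-")]
        assert methylation_density(sites, seq, "m6A") == 1.0

    def test_duplicate_sites_counted_once(self):
        s = [site(0), site(0)]  # same site called in two samples
        assert methylation_density(s, "AACC", "m6A") == 0.5

    def test_empty_denominator_warns(self):
        with pytest.warns(UserWarning):
            assert methylation_density([], "GGCC", "m6A") == 0.0

    def test_base_mismatch_rejected(self):
        with pytest.raises(ValueError):
            methylation_density([site(2)], "AACC", "m6A")  # C is not an A

    def test_m4c_uses_c_and_g(self):
        # "CCGG": 4 target bases for m4C
        assert methylation_density([site(0, t="m4C")], "CCGG", "m4C") == 0.25


class TestRegionSplit:
    def test_all_sites_in_single_cds(self):
        seq = "AAAAAAAAAA"
        split = region_split([site(2)], [CDS(0, 5)], seq)
        assert split["noncoding"]["m6A"] == 0.0
        assert split["coding"]["m6A"] == pytest.approx(1 / 5)

    def test_cds_covering_genome_equals_genome_wide(self):
        seq = "ACGTACGTAA"
        sites = [site(0), site(4)]
        split = region_split(sites, [CDS(0, len(seq))], seq)
        assert split["coding"]["m6A"] == methylation_density(sites, seq, "m6A")

    def test_weighted_identity_and_conservation(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        cds = [CDS(10, 60), CDS(50, 120)]  # overlapping -> union
        positions = [i for i, b in enumerate(seq) if b == "A"]
        chosen = rng.choice(positions, size=min(15, len(positions)), replace=False)
        sites = [site(int(p)) for p in chosen]
        split = region_split(sites, cds, seq)
        mask = coding_mask(cds, len(seq))
        n_a = {
            "coding": sum(1 for i in range(len(seq)) if mask[i] and seq[i] in "AT"),
            "noncoding": sum(1 for i in range(len(seq)) if not mask[i] and seq[i] in "AT"),
        }
        weighted = (
            split["coding"]["m6A"] * n_a["coding"]
            + split["noncoding"]["m6A"] * n_a["noncoding"]
        ) / (n_a["coding"] + n_a["noncoding"])
        assert weighted == pytest.approx(
            methylation_density(sites, seq, "m6A"), abs=1e-12
        )
        # per-site brute force classification agrees
        n_coding_sites = sum(1 for s in sites if mask[s.position])
        assert split["coding"]["m6A"] == pytest.approx(n_coding_sites / n_a["coding"])
        assert n_coding_sites + sum(
            1 for s in sites if not mask[s.position]
        ) == len(sites)

    def test_out_of_range_cds_rejected(self):
        with pytest.raises(ValueError):
            region_split([], [CDS(0, 100)], "ACGT")


class TestCdsSummary:
    def test_fraction_of_methylated_cds(self):
        cds = [CDS(0, 10), CDS(10, 20)]
        out = cds_summary([site(3)], cds)
        assert out["m6A"]["frac_methylated_cds"] == 0.5
        assert out["m4C"]["frac_methylated_cds"] == 0.0

    def test_zero_sites(self):
        out = cds_summary([], [CDS(0, 10)])
        assert out["m6A"]["frac_methylated_cds"] == 0.0
        assert out["m6A"]["per_cds_ratio"] == [0.0]

    def test_three_cds_hand_count(self):
        cds = [CDS(0, 10), CDS(20, 30), CDS(40, 60)]
        sites = [site(1), site(2), site(25), site(45, t="m4C")]
        out = cds_summary(sites, cds)
        assert out["m6A"]["frac_methylated_cds"] == pytest.approx(2 / 3)
        assert out["m6A"]["per_cds_ratio"] == [0.2, 0.1, 0.0]
        assert out["m4C"]["per_cds_ratio"] == [0.0, 0.0, 0.05]

    def test_genome_length_denominator_variant(self):
        out = cds_summary([site(1)], [CDS(0, 10)], per_genome_length=100)
        assert out["m6A"]["per_cds_ratio"] == [0.01]


class TestFunctionalRates:
    def test_single_genome_trna(self):
        genomes = {"g": ([CDS(0, 10, category="tRNA")], [site(3)])}
        rates = functional_rates(genomes)
        assert rates["tRNA"]["m6A"] == 1.0

    def test_absent_category_excluded(self):
        genomes = {"g": ([CDS(0, 10, category="Lysis")], [])}
        assert "tRNA" not in functional_rates(genomes)

    def test_four_genome_fixture_matches_enumeration(self):
        genomes = {}
        expect_hits = {"Lysis": 0, "tRNA": 0}
        possess = {"Lysis": 0, "tRNA": 0}
        rng = np.random.default_rng(11)
        for i in range(4):
            cds = [CDS(0, 10, category="Lysis"), CDS(20, 30, category="tRNA")]
            sites = []
            if rng.random() < 0.5:
                sites.append(site(2, genome=f"g{i}"))
                expect_hits["Lysis"] += 1
            if rng.random() < 0.5:
                sites.append(site(22, genome=f"g{i}"))
                expect_hits["tRNA"] += 1
            genomes[f"g{i}"] = (cds, sites)
            possess["Lysis"] += 1
            possess["tRNA"] += 1
        rates = functional_rates(genomes)
        for cat in ("Lysis", "tRNA"):
            assert rates[cat]["m6A"] == pytest.approx(
                expect_hits[cat] / possess[cat]
            )


class TestAbundance:
    def test_rpkm_formula(self):
        assert compute_rpkm(1000, 10_000, 1_000_000) == pytest.approx(100.0)
        assert compute_rpkm(0, 5_000, 2_000_000) == 0.0
        assert compute_rpkm(200, 10_000, 1_000_000) == 2 * compute_rpkm(
            100, 10_000, 1_000_000
        )

    def test_rpkm_rejects_degenerate(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            compute_rpkm(1, 100, 0)

    def test_prevalence_threshold_inclusive(self):
        mat = np.array([[0.4, 0.4], [0.5, 0.1], [5.0, 0.5]])
        assert prevalence(mat, 0.5).tolist() == [0, 1, 2]

    def test_prevalence_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        mat = rng.exponential(1.0, size=(10, 30))
        prev = [prevalence(mat, t).sum() for t in (0.1, 0.5, 1.0, 5.0)]
        assert prev == sorted(prev, reverse=True)


class TestPartialCorrelation:
    def test_matches_residual_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            z = rng.normal(size=30)
            x = 0.5 * z + rng.normal(size=30)
            y = -0.3 * z + rng.normal(size=30)
            r, _, _ = partial_pearson(x, y, z)
            rx, ry = residualize(x, z), residualize(y, z)
            r_oracle = stats.pearsonr(rx, ry)[0]
            assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_control_equals_plain_pearson(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=25), rng.normal(size=25)
        z = np.full(25, 3.0)
        r, _, p = partial_pearson(x, y, z)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            partial_pearson(x, np.arange(10.0) ** 2, x)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(10)
        x, y, z = rng.normal(size=(3, 40))
        r1, _, _ = partial_pearson(x, y, z)
        r2, _, _ = partial_pearson(y, x, z)
        assert r1 == pytest.approx(r2, abs=1e-12)
        r3, _, _ = partial_pearson(3 * x - 1, -2 * y + 5, 0.5 * z + 2)
        assert r3 == pytest.approx(-r1, abs=1e-10)  # sign flip from -2y


class TestResidualize:
    def test_exact_linear_relation_gives_zero(self):
        z = np.arange(10.0)
        assert np.allclose(residualize(2 * z + 1, z), 0.0, atol=1e-10)

    def test_mean_zero_and_orthogonal(self):
        rng = np.random.default_rng(12)
        v, z = rng.normal(size=(2, 50))
        r = residualize(v, z)
        assert abs(r.mean()) < 1e-10
        assert abs(np.dot(r, z - z.mean())) < 1e-8

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        v, z = rng.normal(size=(2, 30))
        X = np.column_stack([np.ones(30), z])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        assert np.allclose(residualize(v, z), v - X @ beta, atol=1e-10)

    def test_constant_control_mean_centers(self):
        v = np.array([1.0, 2.0, 3.0, 6.0])
        r = residualize(v, np.full(4, 7.0))
        assert np.allclose(r, v - v.mean())


class TestRarefaction:
    def test_full_fraction_is_exact_total(self):
        records = [("s1", "a"), ("s1", "b"), ("s2", "a")]
        out = rarefaction(records, [1.0])
        assert out[1.0] == 2.0

    def test_monotone_nondecreasing_means(self):
        rng = np.random.default_rng(14)
        records = [
            (f"s{rng.integers(5)}", int(k)) for k in rng.integers(0, 40, size=200)
        ]
        out = rarefaction(records, [0.1, 0.3, 0.5, 0.8, 1.0], reps=50, seed=1)
        vals = [out[f] for f in (0.1, 0.3, 0.5, 0.8, 1.0)]
        assert vals == sorted(vals)

    def test_tiny_fixture_matches_exhaustive_enumeration(self):
        # 4 records, subsample 2: expected unique count averaged over all
        # C(4,2)=6 subsets
        records = [("s1", "a"), ("s2", "a"), ("s1", "b"), ("s2", "c")]
        expected = np.mean(
            [
                len({records[i][1], records[j][1]})
                for i, j in itertools.combinations(range(4), 2)
            ]
        )
        out = rarefaction(records, [0.5], reps=4000, seed=2)
        assert out[0.5] == pytest.approx(expected, rel=0.05)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            rarefaction([("s", "a")], [0.0])
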