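import numpy as np
import pytest

from msatdem.differentiation import (
    PairwiseMatrix,
    dest_locus,
    dest_pair,
    fst_significance,
    matrix_correlation,
    pairwise_dest,
    pairwise_fst,
    theta_pair,
)
from conftest import build_dataset, random_dataset


# ---------------------------------------------------------------------------
# independent brute-force oracle: literal Weir-Cockerham (1984) sums
# ---------------------------------------------------------------------------

def wc_theta_bruteforce(dataset, pop1, pop2):
    """Literal evaluation of the variance-component sums, one allele and
    one population at a time, using explicit Python arithmetic."""
    a_tot = 0.0
    abc_tot = 0.0
    pops = [pop1, pop2]
    r = 2
    for j in range(dataset.n_loci):
        genos = []
        for p in pops:
            rows = []
            for i, ind in enumerate(dataset.individuals):
                if ind.population != p:
                    continue
                x, y = int(dataset.alleles[i, j, 0]), int(dataset.alleles[i, j, 1])
                if x > 0 and y > 0:
                    rows.append((x, y))
            genos.append(rows)
        n1, n2 = len(genos[0]), len(genos[1])
        if n1 == 0 or n2 == 0:
            continue
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        states = sorted({x for rows in genos for g in rows for x in g})
        if len(states) < 2:
            continue
        for s in states:
            p_i, h_i, n_i = [], [], []
            for rows in genos:
                n = len(rows)
                count = sum((g[0] == s) + (g[1] == s) for g in rows)
                het = sum(1 for g in rows if (g[0] == s) != (g[1] == s))
                p_i.append(count / (2 * n))
                h_i.append(het / n)
                n_i.append(n)
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            a_tot += a
            abc_tot += a + b + c
    return a_tot / abc_tot if abc_tot else float("nan")


class TestTheta:
    def test_fixed_difference_is_one(self):
        d = build_dataset(
            {"a": [[[10, 10]], [[10, 10]]], "b": [[[12, 12]], [[12, 12]]]}
        )
        assert theta_pair(d, "a", "b") == pytest.approx(1.0)

    def test_duplicated_population_nonpositive(self):
        rng = np.random.default_rng(5)
        block = rng.integers(10, 14, size=(8, 3, 2))
        d = build_dataset({"a": block, "b": block})
        assert theta_pair(d, "a", "b") <= 1e-9

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            d = random_dataset(rng)
            got = theta_pair(d, "P1", "P2")
            want = wc_theta_bruteforce(d, "P1", "P2")
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(9)
        d = random_dataset(rng, missing_rate=0.0)
        th = theta_pair(d, "P1", "P2")
        relab = build_dataset(
            {
                "P2": d.alleles[[i for i, x in enumerate(d.individuals) if x.population == "P2"]] * 3 + 1,
                "P1": d.alleles[[i for i, x in enumerate(d.individuals) if x.population == "P1"]] * 3 + 1,
            }
        )
        assert theta_pair(relab, "P2", "P1") == pytest.approx(th, abs=1e-12)

    def test_monotone_in_divergence_time(self):
        """Pairwise theta grows with split depth (drift accumulates)."""
        from msatdem.demography import Scenario, PriorSpec, DemographicEvent, ParameterDraw, MERGE
        from msatdem.coalsim import SampleConfig, MutationModel, simulate_dataset, default_loci

        def mean_theta(t_split, reps=10):
            sc = Scenario(
                "two",
                {"a": "N", "b": "N"},
                [DemographicEvent(MERGE, "t", derived="b", ancestor="a")],
                [PriorSpec("N", 999.0, 1001.0), PriorSpec("t", t_split - 1, t_split + 1)],
            )
            draw = ParameterDraw({"N": 1000.0, "t": float(t_split)}, "two")
            cfg = SampleConfig({"a": (8, 0), "b": (8, 0)})
            mut = MutationModel(5e-4, range_bound=40)
            vals = []
            for rep in range(reps):
                d = simulate_dataset(sc, draw, cfg, default_loci(6), mut, seed=rep)
                vals.append(theta_pair(d, "a", "b"))
            return float(np.mean(vals))

        t_low, t_mid, t_high = mean_theta(80), mean_theta(800), mean_theta(4000)
        assert t_low < t_mid < t_high


class TestSignificance:
    def test_fixed_pair_minimum_p(self):
        # large enough that no permutation re-creates the original split
        d = build_dataset(
            {"a": [[[10, 10]]] * 12, "b": [[[12, 12]]] * 12}
        )
        res = fst_significance(d, permutations=999, seed=0)
        assert res.p_values[0, 1] == pytest.approx(1 / 1000)
        assert res.significant[0, 1]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        d = random_dataset(rng)
        r1 = fst_significance(d, permutations=199, seed=5)
        r2 = fst_significance(d, permutations=199, seed=5)
        assert np.array_equal(r1.p_values, r2.p_values, equal_nan=True)

    def test_panmictic_rarely_flagged(self):
        """Two samples from one panmictic pool are almost never called
        differentiated at alpha = 0.001."""
        rng = np.random.default_rng(11)
        flags = 0
        for rep in range(20):
            pool = rng.integers(10, 16, size=(20, 4, 2))
            d = build_dataset({"a": pool[:10], "b": pool[10:]})
            res = fst_significance(d, permutations=999, alpha=0.001, seed=rep)
            flags += int(res.significant[0, 1])
        assert flags <= 1


class TestDest:
    def test_disjoint_alleles_is_one(self):
        # internally polymorphic, fully disjoint allele sets
        a = [[[10, 11]], [[10, 11]], [[11, 10]], [[10, 11]]] * 5
        b = [[[20, 21]], [[20, 21]], [[21, 20]], [[20, 21]]] * 5
        d = build_dataset({"a": a, "b": b})
        assert dest_pair(d, "a", "b") == pytest.approx(1.0, abs=1e-9)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        pool = rng.integers(10, 16, size=(400, 3, 2))
        d = build_dataset({"a": pool[:200], "b": pool[200:]})
        assert abs(dest_pair(d, "a", "b")) < 0.05

    def test_locus_formula_hand_oracle(self):
        """Nei-Chesser corrected D for p1=(.6,.4), p2=(.2,.8), n=10 each,
        evaluated independently with explicit arithmetic."""
        ntilde = 10.0
        hs_obs = 1 - ((0.6**2 + 0.4**2) + (0.2**2 + 0.8**2)) / 2
        hs = (2 * ntilde / (2 * ntilde - 1)) * hs_obs
        pbar = [(0.6 + 0.2) / 2, (0.4 + 0.8) / 2]
        ht = (1 - sum(p * p for p in pbar)) + hs / (2 * ntilde * 2)
        expect = (ht - hs) / (1 - hs) * 2
        freqs = np.array([[0.6, 0.4], [0.2, 0.8]])
        got = dest_locus(freqs, np.array([10.0, 10.0]))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_harmonic_le_arithmetic(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = random_dataset(rng, max_ind=8, missing_rate=0.0)
            per_locus = []
            from msatdem.differentiation import _freqs_and_sizes

            m1, m2 = d.population_mask("P1"), d.population_mask("P2")
            for j in range(d.n_loci):
                fs = _freqs_and_sizes(d, [m1, m2], j)
                if fs is not None:
                    v = dest_locus(*fs)
                    if not np.isnan(v):
                        per_locus.append(v)
            if per_locus and all(v > 0 for v in per_locus):
                harm = dest_pair(d, "P1", "P2")
                assert harm <= np.mean(per_locus) + 1e-12

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(21)
        d = random_dataset(rng, max_ind=8, n_loci=4, missing_rate=0.0)
        res = pairwise_dest(d, bootstrap=200, seed=1)
        assert res.ci_low[0, 1] <= res.ci_high[0, 1]


class TestMatrixCorrelation:
    def _mat(self, values):
        return PairwiseMatrix(["a", "b", "c", "d"], np.asarray(values))

    def _random(self, rng):
        n = 4
        v = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i):
                v[i, j] = v[j, i] = rng.random()
        return self._mat(v)

    def test_self_correlation_one(self):
        rng = np.random.default_rng(0)
        m = self._random(rng)
        assert matrix_correlation(m, m) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        m = self._random(rng)
        m2 = self._mat(2.5 * m.values + 0.3)
        assert matrix_correlation(m, m2) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        m1, m2 = self._random(rng), self._random(rng)
        x, y = m1.lower_triangle(), m2.lower_triangle()
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert matrix_correlation(m1, m2) == pytest.approx(expect, abs=1e-12)

    def test_undefined_cells_error(self):
        m1 = self._random(np.random.default_rng(3))
        v = m1.values.copy()
        v[1, 0] = v[0, 1] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            matrix_correlation(self._mat(v), m1)


def test_fst_below_dest_above_diagonal(paper_fixture):
    from msatdem.differentiation import combined_table
    from msatdem.genepop import drop_failed_loci

    d, _ = paper_fixture
    d19, _ = drop_failed_loci(d)
    fst = pairwise_fst(d19)
    dest = pairwise_dest(d19, bootstrap=0)
    tab = combined_table(fst, dest)
    assert tab.iloc[3, 0] == pytest.approx(fst.values[3, 0])
    assert tab.iloc[0, 3] == pytest.approx(dest.values[0, 3])
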