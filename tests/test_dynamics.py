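import numpy as np
import pytest

from synspread import (
    Connectome,
    GeneExpressionProfile,
    RegionAtlas,
    SeedSpec,
    SpreadParameters,
    build_seed_vector,
    gene_modulated_connectome,
    ode_oracle,
    predict_pathology,
)
from tests.conftest import random_connectome


class TestSeedVector:
    def test_single_seed(self):
        atlas = RegionAtlas(("A", "B", "C"))
        x0 = build_seed_vector(atlas, SeedSpec(("B",), 0.1))
        np.testing.assert_array_equal(x0, [0.0, 0.1, 0.0])

    def test_multiple_seeds_sum(self):
        atlas = RegionAtlas(("A", "B", "C"))
        x0 = build_seed_vector(atlas, SeedSpec(("A", "C"), 0.5))
        np.testing.assert_array_equal(x0, [0.5, 0.0, 0.5])
        assert x0.sum() == pytest.approx(0.5 * 2)

    def test_unknown_region_named(self):
        atlas = RegionAtlas(("A", "B", "C"))
        with pytest.raises(KeyError, match="'Z'"):
            build_seed_vector(atlas, SeedSpec(("Z",), 0.1))

    @pytest.mark.parametrize("gamma", [0.0, -0.5, 1.5])
    def test_gamma_bounds(self, gamma):
        with pytest.raises(ValueError):
            SeedSpec(("A",), gamma)


class TestGeneModulation:
    @pytest.fixture
    def conn(self):
        return Connectome(RegionAtlas(("A", "B")), np.array([[0.0, 2.0], [3.0, 0.0]]))

    @pytest.fixture
    def gene(self):
        return GeneExpressionProfile("g", np.array([2.0, 1.0]))

    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("outgoing", [[0, 4], [3, 0]]),
            ("incoming", [[0, 2], [6, 0]]),
            ("combined", [[0, 4], [6, 0]]),
        ],
    )
    def test_hand_computed(self, conn, gene, mode, expected):
        np.testing.assert_allclose(
            gene_modulated_connectome(conn, gene, mode).weights, expected
        )

    def test_length_mismatch_rejected(self, conn):
        with pytest.raises(ValueError, match="length"):
            gene_modulated_connectome(
                conn, GeneExpressionProfile("g", np.ones(3)), "outgoing"
            )

    def test_global_mode_rejected(self, conn, gene):
        with pytest.raises(ValueError):
            gene_modulated_connectome(conn, gene, "global")

    def test_profile_rejects_bad_vectors(self):
        with pytest.raises(ValueError):
            GeneExpressionProfile("g", np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            GeneExpressionProfile("g", np.zeros(2))


class TestPredict:
    def test_identity_dynamics(self, conn_ab):
        params = SpreadParameters(alpha=0.0, beta=0.0, gamma=0.1, s=0.5)
        pred = predict_pathology(conn_ab, params, SeedSpec(("A",), 0.1), (3.0, 6.0))
        assert pred.ok
        np.testing.assert_allclose(pred.values, [[0.1, 0.0], [0.1, 0.0]])

    def test_scalar_growth_closed_form(self, conn_ab):
        # no diffusion: seeded entry grows as gamma * e^{alpha t}
        params = SpreadParameters(alpha=0.33, beta=0.0, gamma=0.1, s=1.0)
        pred = predict_pathology(conn_ab, params, SeedSpec(("A",), 0.1), (3.0,))
        assert pred.values[0, 0] == pytest.approx(0.1 * np.exp(0.99), rel=1e-12)
        assert pred.values[0, 1] == 0.0

    def test_two_region_retrograde_half_life(self, conn_ab):
        # mass placed at B flows retrogradely along A->B; at t=ln2 it has split evenly
        params = SpreadParameters(alpha=0.0, beta=1.0, gamma=1.0, s=1.0)
        pred = predict_pathology(conn_ab, params, SeedSpec(("B",), 1.0), (np.log(2.0),))
        np.testing.assert_allclose(pred.values[0], [0.5, 0.5], rtol=1e-12)

    def test_overflow_reports_failed_status(self, conn_ab):
        params = SpreadParameters(alpha=1.0, beta=1.0, gamma=1.0, s=1.0)
        gene = GeneExpressionProfile("huge", np.array([1e300, 1.0]))
        pred = predict_pathology(
            conn_ab, params, SeedSpec(("B",), 1.0), (3.0,), gene=gene, mode="outgoing"
        )
        assert pred.status == "failed"
        assert pred.diagnostic


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        conn = random_connectome(rng, n=10)
        params = SpreadParameters(
            alpha=float(rng.uniform(-1, 1)),
            beta=float(rng.uniform(0, 2)),
            gamma=float(rng.uniform(0.05, 1)),
            s=float(rng.uniform(0, 1)),
        )
        seed_spec = SeedSpec((conn.atlas.region_ids[0],), params.gamma)
        closed = predict_pathology(conn, params, seed_spec, (3.0, 6.0))
        ode = ode_oracle(conn, params, seed_spec, (3.0, 6.0))
        denom = np.maximum(np.abs(ode.values), 1e-9 * np.abs(ode.values).max())
        assert np.max(np.abs(closed.values - ode.values) / denom) < 1e-6

    def test_oracle_conserves_mass_without_amplification(self, rng):
        conn = random_connectome(rng, n=8)
        params = SpreadParameters(alpha=0.0, beta=1.0, gamma=0.3, s=0.7)
        seed_spec = SeedSpec((conn.atlas.region_ids[2],), 0.3)
        ode = ode_oracle(conn, params, seed_spec, (5.0,))
        assert ode.values[0].sum() == pytest.approx(0.3, abs=1e-8)


class TestInvariants:
    def test_conservation_and_growth_factor(self, rng):
        conn = random_connectome(rng, n=12)
        seed_spec = SeedSpec((conn.atlas.region_ids[0],), 0.2)
        for alpha in (0.0, 0.4, -0.3):
            params = SpreadParameters(alpha=alpha, beta=0.8, gamma=0.2, s=0.6)
            pred = predict_pathology(conn, params, seed_spec, (3.0, 6.0))
            for t, row in zip(pred.times, pred.values):
                assert row.sum() == pytest.approx(0.2 * np.exp(alpha * t), rel=1e-9)

    def test_nonnegativity(self, rng):
        conn = random_connectome(rng, n=12)
        params = SpreadParameters(alpha=-0.5, beta=2.0, gamma=0.9, s=0.3)
        pred = predict_pathology(conn, params, SeedSpec((conn.atlas.region_ids[3],), 0.9), (6.0,))
        assert np.all(pred.values >= 0)

    def test_direction_symmetry(self, rng):
        conn = random_connectome(rng, n=10)
        seed_spec = SeedSpec((conn.atlas.region_ids[1],), 0.5)
        for s in (0.0, 0.25, 0.8, 1.0):
            p1 = predict_pathology(
                conn, SpreadParameters(0.1, 1.0, 0.5, s), seed_spec, (3.0,)
            )
            p2 = predict_pathology(
                conn.transpose(), SpreadParameters(0.1, 1.0, 0.5, 1.0 - s), seed_spec, (3.0,)
            )
            np.testing.assert_array_equal(p1.values, p2.values)

    def test_uniform_gene_scale_absorption(self, rng):
        # a constant gene vector c rescales beta by c (outgoing/incoming) or c^2 (combined)
        conn = random_connectome(rng, n=8)
        seed_spec = SeedSpec((conn.atlas.region_ids[0],), 0.4)
        c = 2.0
        gene = GeneExpressionProfile("const", np.full(8, c))
        base_beta = 0.5
        for mode, factor in (("outgoing", c), ("incoming", c), ("combined", c**2)):
            modulated = predict_pathology(
                conn, SpreadParameters(0.2, base_beta, 0.4, 0.7), seed_spec, (3.0,),
                gene=gene, mode=mode,
            )
            rescaled = predict_pathology(
                conn, SpreadParameters(0.2, base_beta * factor, 0.4, 0.7), seed_spec, (3.0,)
            )
            np.testing.assert_allclose(modulated.values, rescaled.values, rtol=1e-9)
        unit = GeneExpressionProfile("one", np.ones(8))
        for mode in ("outgoing", "incoming", "combined"):
            same = predict_pathology(
                conn, SpreadParameters(0.2, base_beta, 0.4, 0.7), seed_spec, (3.0,),
                gene=unit, mode=mode,
            )
            base = predict_pathology(
                conn, SpreadParameters(0.2, base_beta, 0.4, 0.7), seed_spec, (3.0,)
            )
            np.testing.assert_allclose(same.values, base.values, rtol=1e-12)

    def test_semigroup(self, rng):
        from scipy.linalg import expm

        from synspread.dynamics import generator_matrix

        conn = random_connectome(rng, n=9)
        params = SpreadParameters(0.1, 0.7, 0.3, 0.4)
        seed_spec = SeedSpec((conn.atlas.region_ids[0],), 0.3)
        pred = predict_pathology(conn, params, seed_spec, (2.0, 5.0))
        a = generator_matrix(conn.weights, params.alpha, params.beta, params.s)
        stepped = expm(a * 3.0) @ pred.values[0]
        np.testing.assert_allclose(stepped, pred.values[1], rtol=1e-9)
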