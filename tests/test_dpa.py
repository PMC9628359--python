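"""The allosteric D-value: closed form vs dense oracle, and KL properties."""

import numpy as np
import pytest

from mdpa import build_hessian, decompose
from mdpa.dpa import PerturbationModel, attachments, d_value, score_layer
from mdpa.surface import build_layer
from mdpa.synthetic import make_two_particle_system


def dense_kl_oracle(network, point, model):
    """KL divergence by full-matrix arithmetic, independent of the low-rank path.

    Builds ΔH explicitly, projects onto the internal subspace, and evaluates
    D = ½[ln det(H′H⁺) + tr(H H′⁻¹) − n_int] in the internal eigenbasis.
    """
    H = network.hessian
    w, v = np.linalg.eigh(H)
    rigid = w < 1e-8 * w.max()
    U = v[:, ~rigid]
    lam = w[~rigid]

    X = network.structure.coords
    n = X.shape[0]
    dH = np.zeros_like(H)
    p = np.asarray(point, dtype=float)
    for i in range(n):
        r = p - X[i]
        d = np.linalg.norm(r)
        if 1e-12 < d <= model.attach_cutoff_rp:
            u = r / d
            dH[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += model.k_perturb * np.outer(u, u)
    if not dH.any():
        return 0.0
    A = U.T @ (H + dH) @ U  # U already spans the internal subspace: P·ΔH·P ↦ UᵀΔH U
    sign, logdet_A = np.linalg.slogdet(A)
    assert sign > 0
    logdet_ratio = logdet_A - np.sum(np.log(lam))
    trace_term = np.trace(np.diag(lam) @ np.linalg.inv(A))
    return 0.5 * (logdet_ratio + trace_term - lam.size)


@pytest.fixture(scope="module")
def pair_network():
    return decompose(build_hessian(make_two_particle_system(third_atom=True)))


@pytest.fixture(scope="module")
def model():
    return PerturbationModel()


class TestAttachments:
    def test_far_point_empty(self, toy, model):
        idx, units, d = attachments(np.array([500.0, 0, 0]), toy.structure, model)
        assert idx.size == 0

    def test_equidistant_pair_opposite_projections(self, model):
        st = make_two_particle_system()
        point = np.array([1.9, 2.0, 0.0])  # midway above the pair
        idx, units, d = attachments(point, st, model)
        assert idx.tolist() == [0, 1]
        assert units[0, 0] == pytest.approx(-units[1, 0])  # opposite x components
        assert d[0] == pytest.approx(d[1])

    def test_matches_bruteforce_filter(self, toy, model):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = rng.uniform(-15, 15, size=3)
            idx, units, d = attachments(p, toy.structure, model)
            expected = [
                i for i, x in enumerate(toy.structure.coords)
                if 1e-12 < np.linalg.norm(p - x) <= model.attach_cutoff_rp
            ]
            assert idx.tolist() == expected


class TestDValue:
    def test_zero_spring_constant_gives_zero(self, pair_network):
        m = PerturbationModel(k_perturb=0.0)
        assert d_value(pair_network, np.array([1.9, 3.0, 0.0]), m) == 0.0

    def test_far_point_gives_zero(self, pair_network, model):
        assert d_value(pair_network, np.array([100.0, 0, 0]), model) == 0.0

    def test_single_attachment_closed_form(self, pair_network):
        """One spring: D = ½[ln(1+g) − g/(1+g)] with g = k·uᵀH⁺u."""
        model = PerturbationModel(attach_cutoff_rp=3.0, k_perturb=1.7)
        point = np.array([0.0, 0.0, 2.5])  # within 3 Å of atom 0 only
        idx, units, _ = attachments(point, pair_network.structure, model)
        assert idx.size == 1
        # independent g via dense pseudo-inverse
        w, v = np.linalg.eigh(pair_network.hessian)
        keep = w > 1e-8 * w.max()
        Hplus = (v[:, keep] / w[keep]) @ v[:, keep].T
        e = np.zeros(3 * pair_network.n_atoms)
        e[3 * idx[0] : 3 * idx[0] + 3] = units[0]
        g = model.k_perturb * (e @ Hplus @ e)
        expected = 0.5 * (np.log1p(g) - g / (1.0 + g))
        assert d_value(pair_network, point, model) == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_oracle_on_small_fixture(self, small_network, model):
        """Low-rank formula vs full projected-Hessian KL on every surface point."""
        layer = build_layer(small_network.structure, [], samples_per_sphere=24, seed=2)
        worst = 0.0
        for p in layer.coords:
            fast = d_value(small_network, p, model)
            dense = dense_kl_oracle(small_network, p, model)
            worst = max(worst, abs(fast - dense))
        assert worst <= 1e-8

    def test_nonnegative_everywhere(self, small_network, model):
        rng = np.random.default_rng(3)
        for _ in range(40):
            p = rng.uniform(-12, 12, size=3)
            assert d_value(small_network, p, model) >= 0.0

    def test_monotone_in_spring_constant(self, small_network):
        point = small_network.structure.coords[0] + np.array([0.0, 4.0, 0.0])
        values = [
            d_value(small_network, point, PerturbationModel(k_perturb=k))
            for k in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert values[0] == 0.0
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] > 0

    def test_rigid_transform_invariance(self, small_network, model):
        from scipy.spatial.transform import Rotation

        point = small_network.structure.coords[7] + np.array([3.0, 1.0, -2.0])
        d0 = d_value(small_network, point, model)
        R = Rotation.random(random_state=np.random.default_rng(8)).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = small_network.structure.with_coords(small_network.structure.coords @ R.T + t)
        net2 = decompose(build_hessian(moved))
        d1 = d_value(net2, point @ R.T + t, model)
        assert d1 == pytest.approx(d0, abs=1e-8)


class TestScoreLayer:
    def test_equals_pointwise_calls(self, small_network, model):
        layer = build_layer(small_network.structure, [], samples_per_sphere=24, seed=4)
        score_layer(small_network, layer, model)
        for i in range(layer.n_points):
            assert layer.d_values[i] == pytest.approx(
                d_value(small_network, layer.coords[i], model), abs=1e-12
            )

    def test_permutation_equivariance(self, small_network, model):
        layer = build_layer(small_network.structure, [], samples_per_sphere=24, seed=5)
        score_layer(small_network, layer, model)
        perm = np.random.default_rng(0).permutation(layer.n_points)
        from mdpa.surface import SurfaceLayer

        shuffled = SurfaceLayer(
            layer_index=1, coords=layer.coords[perm], probe_radius=1.5,
            sphere_radius_protein=3.0, sphere_radius_virtual=1.5,
            samples_per_sphere=24, seed=5,
        )
        score_layer(small_network, shuffled, model)
        np.testing.assert_allclose(shuffled.d_values, layer.d_values[perm], atol=1e-12)

    def test_far_layer_scores_zero(self, small_network, model):
        from mdpa.surface import SurfaceLayer

        far = SurfaceLayer(
            layer_index=1, coords=np.array([[200.0, 0, 0], [0, 300.0, 0]]),
            probe_radius=1.5, sphere_radius_protein=3.0, sphere_radius_virtual=1.5,
            samples_per_sphere=24, seed=0,
        )
        score_layer(small_network, far, model)
        assert (far.d_values == 0).all()
        assert (far.n_attachments == 0).all()
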