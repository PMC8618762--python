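import numpy as np
import pytest

from kqfod.dictionary import angular_neighbors, build_dictionary, sample_hemisphere
from kqfod.forward_model import (
    SplitFOD,
    TissueMaps,
    adjoint_A,
    apply_A,
    data_fidelity,
    embed,
    restrict,
    spectral_norm,
)
from kqfod.phantom import make_phantom, make_phase_maps, simulate_acquisition, simulate_coils
from kqfod.sampling import masks_for_scheme, qspace_single_shell
from kqfod.solver import (
    SolveDiagnostics,
    SolverConfig,
    init_tau,
    project_positive,
    project_weighted_l1_positive,
    reweighted_solve,
    spatio_angular_blur,
    stochastic_fb,
    update_tau,
)


def _qp_oracle(v, w, kappa, tol=1e-12):
    """Projection onto {x >= 0, w.x <= kappa} by bisection on the KKT
    multiplier — independent of the sorting-based production path."""
    x = np.maximum(v, 0.0)
    if np.dot(w, x) <= kappa:
        return x
    lo, hi = 0.0, max(np.max(v[w > 0] / w[w > 0]), 1.0)
    for _ in range(200):
        mu = (lo + hi) / 2
        g = np.dot(w, np.maximum(0.0, v - mu * w))
        if g > kappa:
            lo = mu
        else:
            hi = mu
    mu = (lo + hi) / 2
    x = np.maximum(0.0, v - mu * w)
    x[w == 0] = np.maximum(v[w == 0], 0.0)
    return x


class TestProjections:
    def test_positive_projection_basic(self):
        v = np.array([-1.0, 2.0])
        assert np.array_equal(project_positive(v), [0.0, 2.0])
        assert np.array_equal(project_positive(project_positive(v)),
                              project_positive(v))

    def test_weighted_ball_known_instance(self):
        out = project_weighted_l1_positive(
            np.array([3.0, 1.0]), np.array([1.0, 1.0]), 2.0
        )
        assert np.allclose(out, [2.0, 0.0], atol=1e-12)

    def test_feasible_point_unchanged(self):
        v = np.array([[0.1, 0.2], [0.0, 0.3]])
        out = project_weighted_l1_positive(v, np.ones_like(v), 10.0)
        assert np.array_equal(out, v)

    def test_all_negative_goes_to_origin(self):
        v = -np.ones(5)
        out = project_weighted_l1_positive(v, np.ones(5), 3.0)
        assert np.array_equal(out, np.zeros(5))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(12):
            m = rng.integers(2, 21)
            v = rng.standard_normal(m) * rng.uniform(0.5, 3)
            w = rng.uniform(0, 2, size=m)
            if rng.random() < 0.3:
                w[rng.integers(m)] = 0.0
            kappa = rng.uniform(0, 2)
            got = project_weighted_l1_positive(v, w, kappa)
            ref = _qp_oracle(v, w, kappa)
            assert np.allclose(got, ref, atol=1e-8)
            assert np.all(got >= 0)
            assert np.dot(w, got) <= kappa * (1 + 1e-9) + 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_nonexpansive(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = 15
        w = rng.uniform(0.1, 2, size=m)
        kappa = 1.5
        u = rng.standard_normal(m) * 2
        v = rng.standard_normal(m) * 2
        pu = project_weighted_l1_positive(u, w, kappa)
        pv = project_weighted_l1_positive(v, w, kappa)
        assert np.allclose(
            project_weighted_l1_positive(pu, w, kappa), pu, atol=1e-10
        )
        assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-12

    def test_zero_weights_reduce_to_orthant(self):
        v = np.array([1.0, -2.0, 3.0])
        out = project_weighted_l1_positive(v, np.zeros(3), 0.0)
        assert np.array_equal(out, project_positive(v))


class TestTau:
    def test_update_floor(self):
        assert update_tau(10e-6, 1e-6) == pytest.approx(1e-6)
        assert update_tau(1000e-6, 1e-6) == pytest.approx(100e-6)

    def test_init_is_variance_with_fallback(self):
        B = np.array([[0.0, 1.0], [2.0, 3.0]])
        assert init_tau(B, 1e-6) == pytest.approx(np.var(B))
        assert init_tau(np.full((3, 3), 2.0), 1e-6) == 1e-6


class TestWeights:
    def _tissues_full_wm(self, shape):
        wm = np.ones(shape, dtype=bool)
        return TissueMaps(wm=wm, gm=np.zeros_like(wm), csf=np.zeros_like(wm))

    def test_zero_field_gives_zero_blur(self, dirs48):
        shape = (4, 4, 3)
        tissues = self._tissues_full_wm(shape)
        ang = angular_neighbors(dirs48, 15.0)
        S1 = np.zeros((dirs48.n, int(np.prod(shape))))
        B = spatio_angular_blur(S1, tissues, ang, shape)
        assert not B.any()

    def test_uniform_field_closed_form(self, dirs48):
        # constant S1 = s: B(d, v) = s * |cone(d)| for interior voxels
        shape = (5, 5, 5)
        tissues = self._tissues_full_wm(shape)
        ang = angular_neighbors(dirs48, 15.0)
        s = 0.7
        S1 = np.full((dirs48.n, int(np.prod(shape))), s)
        B = spatio_angular_blur(S1, tissues, ang, shape)
        cone_sizes = np.array([len(a) for a in ang.adjacency])
        interior = np.ravel_multi_index((2, 2, 2), shape)
        j = list(tissues.wm_idx).index(interior)
        assert np.allclose(B[:, j], s * cone_sizes, atol=1e-12)

    def test_isolated_spike_weighted_more_than_tube(self, dirs48):
        # same amplitude: an isolated spike gets a higher weight (smaller
        # blur) than a voxel inside a spatially coherent tube
        shape = (3, 3, 5)
        tissues = self._tissues_full_wm(shape)
        ang = angular_neighbors(dirs48, 15.0)
        N = int(np.prod(shape))
        d = 7
        spike = np.zeros((dirs48.n, N))
        spike[d, np.ravel_multi_index((1, 1, 2), shape)] = 1.0
        tube = np.zeros((dirs48.n, N))
        for z in range(5):
            tube[d, np.ravel_multi_index((1, 1, z), shape)] = 1.0
        Bs = spatio_angular_blur(spike, tissues, ang, shape)
        Bt = spatio_angular_blur(tube, tissues, ang, shape)
        j = np.ravel_multi_index((1, 1, 2), shape)
        tau = 1e-3
        assert 1 / (tau + Bs[d, j]) > 1 / (tau + Bt[d, j])


@pytest.fixture(scope="module")
def tiny_problem():
    """8x8x4 phantom, M=6, C=4, noisy, fully sampled — small enough for
    exhaustive solver comparisons."""
    dirs = sample_hemisphere(24, seed=0)
    phantom = make_phantom((8, 8, 4), dirs=dirs, seed=2)
    scheme = qspace_single_shell(6, seed=0)
    dic = build_dictionary(scheme, dirs)
    masks = masks_for_scheme(scheme, phantom.shape, factor=1.0)
    coils = simulate_coils(phantom.shape, C=4, seed=0)
    phases = make_phase_maps(phantom.shape, scheme.M, 4, seed=0)
    kdata, model = simulate_acquisition(
        phantom, dic, scheme, masks, coils, phases, snr=30.0, seed=3
    )
    tissues = TissueMaps.from_dict(phantom.tissue_maps)
    return {
        "phantom": phantom, "model": model, "kdata": kdata,
        "tissues": tissues, "dirs": dirs,
    }


def _plain_fb_reference(Y, model, tissues, W, kappa, step, n_iter):
    """Textbook projected-gradient loop written against the public operator
    API only — the reference the production iteration must bit-match."""
    n = model.dictionary.matrix.shape[1] - 2
    S = SplitFOD.zeros(n, tissues)
    for _ in range(n_iter):
        X = embed(S, tissues, n, model.N)
        pred = apply_A(X, model)
        for q in range(model.M):
            pred.samples[q] = pred.samples[q] - Y.samples[q]
        G = restrict(2.0 * adjoint_A(pred, model), tissues)
        V = S.axpy(-step, G)
        S = SplitFOD(
            project_weighted_l1_positive(V.S1, W, kappa),
            project_positive(V.S2),
            project_positive(V.S3),
        )
    return S


class TestStochasticFB:
    def test_deterministic_bit_matches_plain_reference(self, tiny_problem):
        model, kdata, tissues = (
            tiny_problem["model"], tiny_problem["kdata"], tiny_problem["tissues"]
        )
        n = model.dictionary.matrix.shape[1] - 2
        W = np.ones((n, tissues.wm_idx.size))
        norm_A = spectral_norm(model, tissues, seed=0)
        step = 1.9 / (2 * norm_A**2)
        kappa = 4.0 * tissues.wm_idx.size
        cfg = SolverConfig(max_iter=60, nu=1e-15, seed=0, kappa=kappa)
        got = stochastic_fb(kdata, model, tissues, W, cfg, step=step)
        ref = _plain_fb_reference(kdata, model, tissues, W, kappa, step, 60)
        assert np.array_equal(got.S1, ref.S1)
        assert np.array_equal(got.S2, ref.S2)
        assert np.array_equal(got.S3, ref.S3)

    def test_stochastic_reaches_deterministic_objective(self):
        # overdetermined per-voxel system (n + 2 < M + 1) makes the data fit
        # strongly convex, so both variants converge to the unique minimum
        dirs = sample_hemisphere(4, seed=0)
        phantom = make_phantom((8, 8, 4), dirs=dirs, seed=2)
        scheme = qspace_single_shell(6, seed=0)
        from kqfod.dictionary import build_dictionary as _bd

        dic = _bd(scheme, dirs)
        masks = masks_for_scheme(scheme, phantom.shape, factor=1.0)
        coils = simulate_coils(phantom.shape, C=4, seed=0)
        phases = make_phase_maps(phantom.shape, scheme.M, 4, seed=0)
        kdata, model = simulate_acquisition(
            phantom, dic, scheme, masks, coils, phases, snr=30.0, seed=3
        )
        tissues = TissueMaps.from_dict(phantom.tissue_maps)
        n = dirs.n
        W = np.ones((n, tissues.wm_idx.size))
        norm_A = spectral_norm(model, tissues, seed=0)
        step = 1.9 / (2 * norm_A**2)
        det_cfg = SolverConfig(max_iter=4000, nu=1e-10, seed=0)
        det = stochastic_fb(kdata, model, tissues, W, det_cfg, step=step)
        f_det = data_fidelity(det, kdata, model, tissues)
        # 2 fixed + 1 random of 4 coils
        sto_cfg = SolverConfig(
            max_iter=8000, nu=1e-10, seed=7, n_fixed=2, n_random=1
        )
        sto = stochastic_fb(kdata, model, tissues, W, sto_cfg, step=step)
        f_sto = data_fidelity(sto, kdata, model, tissues)
        assert abs(f_sto - f_det) <= 1e-6 * f_det

    def test_noiseless_objective_vanishes(self):
        # overdetermined per-voxel system (M > n+2), noiseless, full masks:
        # the FB iterate drives the data fit to numerical zero
        dirs = sample_hemisphere(4, seed=0)
        phantom = make_phantom((8, 8, 4), dirs=dirs, seed=2)
        scheme = qspace_single_shell(12, seed=0)
        dic = build_dictionary(scheme, dirs)
        masks = masks_for_scheme(scheme, phantom.shape, factor=1.0)
        coils = simulate_coils(phantom.shape, C=2, seed=0)
        phases = make_phase_maps(phantom.shape, scheme.M, 2, seed=0)
        kdata, model = simulate_acquisition(
            phantom, dic, scheme, masks, coils, phases, snr=np.inf, seed=0
        )
        tissues = TissueMaps.from_dict(phantom.tissue_maps)
        n = dirs.n
        W = np.ones((n, tissues.wm_idx.size))
        cfg = SolverConfig(max_iter=4000, nu=1e-12, seed=0, nesterov=True)
        S = stochastic_fb(kdata, model, tissues, W, cfg)
        f = data_fidelity(S, kdata, model, tissues)
        assert f <= 1e-10 * kdata.norm2()

    def test_divergence_detection(self, tiny_problem):
        # warm-started at the truth the objective sits at the noise floor;
        # an out-of-range step then kicks it far above its initial value
        phantom = tiny_problem["phantom"]
        model, tissues = tiny_problem["model"], tiny_problem["tissues"]
        Y = tiny_problem["kdata"]
        S_true = restrict(phantom.true_fod, tissues)
        n = model.dictionary.matrix.shape[1] - 2
        W = np.ones((n, tissues.wm_idx.size))
        norm_A = spectral_norm(model, tissues, seed=0)
        bad_step = 10.0 / norm_A**2   # far outside the guaranteed range
        cfg = SolverConfig(max_iter=2000, nu=1e-15, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            stochastic_fb(
                Y, model, tissues, W, cfg, S0=S_true, step=bad_step,
                diagnostics=SolveDiagnostics(),
            )

    def test_invalid_subset_size(self, tiny_problem):
        model, kdata, tissues = (
            tiny_problem["model"], tiny_problem["kdata"], tiny_problem["tissues"]
        )
        n = model.dictionary.matrix.shape[1] - 2
        W = np.ones((n, tissues.wm_idx.size))
        cfg = SolverConfig(n_fixed=3, n_random=4)   # 7 > C=4
        with pytest.raises(ValueError):
            stochastic_fb(kdata, model, tissues, W, cfg, step=1e-3)


class TestReweighting:
    def test_single_cycle_equals_unit_weight_solve(self, tiny_problem):
        model, kdata, tissues = (
            tiny_problem["model"], tiny_problem["kdata"], tiny_problem["tissues"]
        )
        n = model.dictionary.matrix.shape[1] - 2
        norm_A = spectral_norm(model, tissues, seed=0)
        step = 1.9 / (2 * norm_A**2)
        cfg = SolverConfig(max_iter=150, nu=1e-12, seed=0, T=1)
        S_rw = reweighted_solve(kdata, model, tissues, cfg)
        W = np.ones((n, tissues.wm_idx.size))
        S_fb = stochastic_fb(kdata, model, tissues, W, cfg, step=step)
        assert np.allclose(S_rw.S1, S_fb.S1, atol=1e-12)

    def test_reweighting_reduces_false_positives(self, tiny_problem):
        from kqfod.peaks import PeakSet, evaluate, extract_peak_field

        model, kdata, tissues = (
            tiny_problem["model"], tiny_problem["kdata"], tiny_problem["tissues"]
        )
        phantom, dirs = tiny_problem["phantom"], tiny_problem["dirs"]
        truth = {v: PeakSet(d, f) for v, (d, f) in phantom.true_peaks.items()}
        reports = {}
        for T in (1, 10):
            cfg = SolverConfig(max_iter=300, nu=1e-4, seed=0, T=T, nesterov=True)
            S = reweighted_solve(kdata, model, tissues, cfg)
            est = extract_peak_field(S.S1, tissues.wm_idx, dirs)
            reports[T] = evaluate(est, truth)
        assert reports[10].FP <= reports[1].FP
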