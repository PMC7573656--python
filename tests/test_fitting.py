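"""Voxelwise estimation: tensor and ball & sticks recovery on noiseless
phantoms, the regularised eigenvalue-gamma fit, beff mapping, and the
orientation-posterior dispersion measure."""

import numpy as np
import pytest

from dwssfp import (
    GammaDiffusivity,
    OrientationSamples,
    Region,
    TissueParams,
    adc_at_beff,
    apparent_diffusivity_at_flip,
    buxton_gamma_signal,
    default_sequences,
    fit_ballsticks,
    fit_gamma_eigenvalues,
    fit_tensor,
    fractional_anisotropy,
    make_ballsticks_phantom,
    make_tensor_phantom,
    map_eigenvalues_to_beff,
    pdd_dispersion,
    posterior_pdd_samples,
    protocol_directions,
    simulate_acquisition,
)
from dwssfp.fitting import FLAG_LOW_SIGNAL, FLAG_ORDERING, _TensorProblem
from conftest import subsample

TRUE_DM = np.array([1.7e-4, 0.8e-4, 0.5e-4])


@pytest.fixture(scope="module")
def gaussian_phantom():
    # Ds = 0 world with an oblique PDD
    reg = [Region("g", lambda s: np.ones(s, bool), Dm=tuple(TRUE_DM),
                  Ds=(0.0, 0.0, 0.0), pdd=(1.0, 1.0, 0.0))]
    return make_tensor_phantom((10, 10, 10), regions=reg)


@pytest.fixture(scope="module")
def dirs23():
    return protocol_directions(n_dw=20, n_nondw=3, seed=11)


@pytest.fixture(scope="module")
def gaussian_data(gaussian_phantom, dirs23, sequences):
    return simulate_acquisition(gaussian_phantom, dirs23, sequences, 0.0, seed=2)


def maps_of(ph, snf=0.0):
    return dict(T1=ph.T1, T2=ph.T2, B1=ph.B1, mask=ph.mask, Snf=snf)


class TestTensorFit:
    def test_noiseless_gaussian_recovery(self, gaussian_phantom, gaussian_data,
                                         dirs23, sequences):
        ph = gaussian_phantom
        vox = subsample(ph.mask, 40, limit=6)
        # exact-q fitting: the simulation applies the true spoiler q
        fit = fit_tensor({94.0: gaussian_data[94.0]}, dirs23, maps_of(ph),
                         {94.0: sequences[94.0]}, mode="single", voxels=vox,
                         spoiler_as_q0=False)
        v1t = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        for idx in zip(*np.nonzero(vox)):
            assert fit.flags[idx] == 0
            assert np.all(np.abs(fit.L[94.0][idx] - TRUE_DM) / TRUE_DM < 0.005)
            ang = np.degrees(np.arccos(np.clip(abs(fit.V[idx][:, 0] @ v1t), 0, 1)))
            assert ang < 1.0

    def test_dual_fit_shares_one_eigenvector_parameterisation(self, sequences, dirs23):
        # the two flips' predictions are generated from literally the same
        # rotation parameters: 11 = 2 x (lnS0 + 3 eigenvalues) + one rotvec
        data = {24.0: np.zeros(len(dirs23)), 94.0: np.zeros(len(dirs23))}
        prob = _TensorProblem(data, dirs23, sequences, 500.0, 30.0, 0.8, 0.0)
        assert prob.n_params == 11
        lnS0, rot, eig = prob.unpack(np.arange(11, dtype=float))
        assert rot.shape == (3,) and eig.shape == (2, 3) and lnS0.shape == (2,)

    def test_dual_gamma_phantom_lhigh_above_llow(self, small_phantom, small_noiseless,
                                                 small_dirs, sequences, small_maps):
        vox = subsample(small_phantom.mask & (small_phantom.B1 > 0.5), 30, limit=5)
        fit = fit_tensor(small_noiseless, small_dirs, small_maps, sequences,
                         mode="dual", voxels=vox)
        for idx in zip(*np.nonzero(vox)):
            assert np.all(fit.L[94.0][idx] > fit.L[24.0][idx])

    def test_noise_floor_voxel_is_flagged(self, small_phantom, small_dirs, sequences):
        ph = small_phantom
        snf = 0.05
        flat = {f: np.full(ph.shape + (len(small_dirs),), snf) for f in (24.0, 94.0)}
        vox = subsample(ph.mask, 200, limit=2)
        fit = fit_tensor(flat, small_dirs, maps_of(ph, snf=snf), sequences,
                         mode="dual", voxels=vox)
        for idx in zip(*np.nonzero(vox)):
            assert fit.flags[idx] & FLAG_LOW_SIGNAL

    def test_under_determined_rejected(self, small_phantom, sequences):
        few = protocol_directions(n_dw=6, n_nondw=0, seed=1)
        data = {94.0: np.zeros(small_phantom.shape + (6,))}
        with pytest.raises(ValueError, match="volumes"):
            fit_tensor(data, few, maps_of(small_phantom), {94.0: sequences[94.0]},
                       mode="single")


class TestApparentDiffusivity:
    def test_gaussian_returns_dm(self, tissue, seq):
        g = GammaDiffusivity(1e-4, 0.0)
        assert apparent_diffusivity_at_flip(g, 40.0, tissue, seq) == 1e-4

    def test_increases_with_flip_angle(self, tissue, sequences):
        g = GammaDiffusivity(1e-4, 1e-4)
        lo = apparent_diffusivity_at_flip(g, 24.0, tissue, sequences[24.0])
        hi = apparent_diffusivity_at_flip(g, 94.0, tissue, sequences[94.0])
        assert hi > lo
        assert lo < g.Dm  # restriction lowers the apparent value

    def test_matches_independent_bisection_oracle(self, tissue, seq):
        # brentq on the adaptive-quadrature signal, coded independently
        from scipy.optimize import brentq
        from dwssfp import buxton_signal

        g = GammaDiffusivity(1e-4, 1e-4)
        for alpha in (24.0, 94.0):
            target = buxton_gamma_signal(alpha, tissue, seq, g)
            oracle = brentq(
                lambda D: buxton_signal(alpha, tissue, seq, D) - target,
                1e-8, 1e-3, xtol=1e-14,
            )
            val = apparent_diffusivity_at_flip(g, alpha, tissue, seq)
            assert val == pytest.approx(oracle, rel=1e-5)


class TestEigenGammaFit:
    def test_gaussian_voxel_collapses_to_point(self, tissue, sequences):
        L = np.array([[1.5e-4, 7e-5, 4e-5]])
        eg = fit_gamma_eigenvalues(L, L, np.array([22.0]), np.array([85.0]),
                                   tissue, sequences[24.0], sequences[94.0])
        assert np.all(np.abs(eg.Dm[0] - L[0]) / L[0] < 0.02)
        assert np.all(eg.Ds[0] < 0.05 * eg.Dm[0])

    @pytest.mark.parametrize("B1", [0.65, 0.95])
    def test_forward_chain_recovery(self, B1, tissue, sequences):
        # L_exp generated from known (Dm, Ds) through the forward chain
        true = [(1.7e-4, 0.85e-4), (0.8e-4, 0.4e-4), (0.5e-4, 0.25e-4)]
        al, ah = 24.0 * B1, 94.0 * B1
        Llow = np.array([[apparent_diffusivity_at_flip(GammaDiffusivity(*t), al,
                                                       tissue, sequences[24.0])
                          for t in true]])
        Lhigh = np.array([[apparent_diffusivity_at_flip(GammaDiffusivity(*t), ah,
                                                        tissue, sequences[94.0])
                           for t in true]])
        eg = fit_gamma_eigenvalues(Llow, Lhigh, np.array([al]), np.array([ah]),
                                   tissue, sequences[24.0], sequences[94.0],
                                   lambda_reg=1.0)
        for i, (dm, _) in enumerate(true):
            assert abs(eg.Dm[0, i] - dm) / dm < 0.05

    def test_default_lambda_is_one(self, tissue, sequences):
        L = np.array([[1.5e-4, 7e-5, 4e-5]])
        eg = fit_gamma_eigenvalues(L, L, np.array([22.0]), np.array([85.0]),
                                   tissue, sequences[24.0], sequences[94.0])
        assert eg.lambda_reg == 1.0


class TestBeffMapping:
    def test_gaussian_identity(self):
        from dwssfp.fitting import EigenGammaFit
        Dm = np.array([[1.5e-4, 7e-5, 4e-5]])
        eig = EigenGammaFit(Dm=Dm, Ds=np.zeros_like(Dm), residual=np.zeros_like(Dm),
                            converged=np.ones_like(Dm, bool), lambda_reg=1.0)
        L, flags = map_eigenvalues_to_beff(eig, 4000.0)
        assert np.allclose(L, Dm)
        assert flags[0] == 0

    def test_matches_scalar_adc(self):
        from dwssfp.fitting import EigenGammaFit
        Dm = np.array([[1.5e-4, 7e-5, 4e-5]])
        Ds = 0.5 * Dm
        eig = EigenGammaFit(Dm=Dm, Ds=Ds, residual=np.zeros_like(Dm),
                            converged=np.ones_like(Dm, bool), lambda_reg=1.0)
        L, _ = map_eigenvalues_to_beff(eig, 4000.0)
        for i in range(3):
            ref = adc_at_beff(4000.0, GammaDiffusivity(Dm[0, i], Ds[0, i]))
            assert L[0, i] == pytest.approx(ref, rel=1e-10)

    def test_fa_preserved_for_gaussian_truth(self):
        from dwssfp.fitting import EigenGammaFit
        Dm = TRUE_DM[None, :]
        eig = EigenGammaFit(Dm=Dm, Ds=np.zeros_like(Dm), residual=np.zeros_like(Dm),
                            converged=np.ones_like(Dm, bool), lambda_reg=1.0)
        L, _ = map_eigenvalues_to_beff(eig, 4000.0)
        # closed-form FA of the ground-truth eigenvalues
        m = TRUE_DM.mean()
        fa_true = np.sqrt(1.5 * ((TRUE_DM - m) ** 2).sum() / (TRUE_DM**2).sum())
        assert fractional_anisotropy(L[0]) == pytest.approx(fa_true, abs=1e-6)

    def test_ordering_violation_flagged_not_reordered(self):
        from dwssfp.fitting import EigenGammaFit
        # strong Ds on L1 pushes the mapped L1 below L2
        Dm = np.array([[1.0e-4, 9.5e-5, 4e-5]])
        Ds = np.array([[2.0e-4, 1e-9, 1e-9]])
        eig = EigenGammaFit(Dm=Dm, Ds=Ds, residual=np.zeros_like(Dm),
                            converged=np.ones_like(Dm, bool), lambda_reg=1.0)
        L, flags = map_eigenvalues_to_beff(eig, 8000.0)
        assert flags[0] & FLAG_ORDERING
        assert L[0, 0] < L[0, 1]  # left as computed


@pytest.fixture(scope="module")
def bs_phantom():
    return make_ballsticks_phantom((8, 8, 8), fractions=(0.5,),
                                   stick_axes=((1.0, 1.0, 0.0),))


@pytest.fixture(scope="module")
def bs_data(bs_phantom, dirs23, sequences):
    return simulate_acquisition(bs_phantom, dirs23, sequences, 0.0, seed=3)


class TestBallSticks:
    def test_single_stick_orientation_recovery(self, bs_phantom, bs_data, dirs23,
                                               sequences):
        vox = subsample(bs_phantom.mask, 50, limit=3)
        fit = fit_ballsticks(bs_data, dirs23, maps_of(bs_phantom), sequences,
                             n_sticks=1, mode="dual", voxels=vox, seed=1)
        vt = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        for idx in zip(*np.nonzero(vox)):
            ang = np.degrees(np.arccos(np.clip(abs(fit.sticks[idx][0] @ vt), 0, 1)))
            assert ang < 2.0
            assert abs(fit.fractions[idx][0] - 0.5) < 0.05

    def test_dual_diffusivities_ordered(self, bs_phantom, bs_data, dirs23, sequences):
        vox = subsample(bs_phantom.mask, 50, limit=3)
        fit = fit_ballsticks(bs_data, dirs23, maps_of(bs_phantom), sequences,
                             n_sticks=1, mode="dual", voxels=vox, seed=1)
        for idx in zip(*np.nonzero(vox)):
            # phantom truth: d at the high flip exceeds d at the low flip
            assert fit.d[94.0][idx] > fit.d[24.0][idx]

    def test_pure_ball_gives_small_fraction(self, dirs23, sequences):
        ph = make_ballsticks_phantom((8, 8, 8), fractions=(0.0,),
                                     stick_axes=((1.0, 0.0, 0.0),))
        data = simulate_acquisition(ph, dirs23, sequences, 0.0, seed=3)
        vox = subsample(ph.mask, 60, limit=2)
        fit = fit_ballsticks(data, dirs23, maps_of(ph), sequences, n_sticks=1,
                             mode="dual", voxels=vox, seed=1)
        for idx in zip(*np.nonzero(vox)):
            assert fit.fractions[idx][0] < 0.05


class TestDispersion:
    def test_identical_and_antipodal_samples(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert pdd_dispersion(OrientationSamples(v)) == pytest.approx(0.0, abs=1e-12)
        v[::2] *= -1
        assert pdd_dispersion(OrientationSamples(v)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sphere_limit(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert pdd_dispersion(OrientationSamples(v)) == pytest.approx(2 / 3, abs=0.01)

    def test_permutation_and_flip_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        d0 = pdd_dispersion(OrientationSamples(v))
        perm = v[rng.permutation(200)].copy()
        signs = rng.choice([-1.0, 1.0], size=(200, 1))
        assert pdd_dispersion(OrientationSamples(perm)) == pytest.approx(d0, rel=1e-12)
        assert pdd_dispersion(OrientationSamples(v * signs)) == pytest.approx(d0, rel=1e-12)

    def test_monotone_under_added_jitter(self):
        rng = np.random.default_rng(2)
        base = np.tile([0.0, 0.0, 1.0], (500, 1))
        prev = -1.0
        for jitter in (0.02, 0.1, 0.3):
            v = base + jitter * rng.normal(size=base.shape)
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            d = pdd_dispersion(OrientationSamples(v))
            assert d > prev
            prev = d

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pdd_dispersion(np.array([[0.0, 0.0, 1.0]]))


class TestPosteriorSamples:
    def test_seeded_chain_is_bit_identical(self, small_phantom, small_dirs,
                                           sequences, small_maps):
        noisy = simulate_acquisition(small_phantom, small_dirs, sequences,
                                     0.001, seed=6)
        idx = tuple(np.array(np.nonzero(small_phantom.B1 > 0.9)).T[0])
        maps = dict(small_maps, Snf=0.001 * np.sqrt(np.pi / 2))
        a = posterior_pdd_samples(noisy, small_dirs, maps, sequences, idx,
                                  n_samples=80, seed=42)
        b = posterior_pdd_samples(noisy, small_dirs, maps, sequences, idx,
                                  n_samples=80, seed=42)
        assert np.array_equal(a.vectors, b.vectors)

    def test_zero_noise_collapses_to_point(self, small_phantom, small_noiseless,
                                           small_dirs, sequences, small_maps):
        idx = tuple(np.array(np.nonzero(small_phantom.B1 > 0.9)).T[0])
        s = posterior_pdd_samples(small_noiseless, small_dirs, small_maps,
                                  sequences, idx, n_samples=60, seed=0)
        assert pdd_dispersion(s) < 1e-3

    def test_doubling_noise_increases_dispersion(self, small_phantom, small_dirs,
                                                 sequences, small_maps):
        idx = tuple(np.array(np.nonzero(small_phantom.B1 > 0.9)).T[0])
        disps = []
        for sigma in (0.002, 0.008):
            noisy = simulate_acquisition(small_phantom, small_dirs, sequences,
                                         sigma, seed=6)
            maps = dict(small_maps, Snf=sigma * np.sqrt(np.pi / 2))
            s = posterior_pdd_samples(noisy, small_dirs, maps, sequences, idx,
                                      n_samples=150, seed=7)
            disps.append(pdd_dispersion(s))
        assert disps[1] > disps[0]
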