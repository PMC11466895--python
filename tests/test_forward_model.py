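import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cryodeform import autodiff as ad
from cryodeform import forward_model as fm
from cryodeform.gaussian_model import GaussianModel, render_density
from cryodeform.io_formats import CTFParams, ParticleStack


class TestCtf:
    def test_dc_value_is_minus_amplitude_contrast(self, typical_ctf):
        arr = fm.ctf_evaluate(typical_ctf, 32, 2.0)
        assert arr[0, 0] == pytest.approx(-typical_ctf.amplitude_contrast)

    def test_pure_amplitude_contrast_limit(self):
        ctf = CTFParams(10000, 10000, 0.0, amplitude_contrast=1.0)
        arr = fm.ctf_evaluate(ctf, 32, 2.0)
        assert arr[0, 0] == pytest.approx(-1.0)
        assert np.all(np.abs(arr) <= 1.0 + 1e-12)

    def test_no_astigmatism_is_rotationally_symmetric(self):
        ctf = CTFParams(15000, 15000, 77.0)
        arr = fm.ctf_evaluate(ctf, 64, 1.5)
        # drop the unmatched Nyquist row/column so rot90 maps the grid
        # onto itself around DC
        sh = np.fft.fftshift(arr)[1:, 1:]
        assert np.abs(sh - np.rot90(sh)).max() < 1e-6

    def test_first_zero_matches_root_solver(self):
        """First CTF zero radius agrees with an independent chi-root solve."""
        ctf = CTFParams(10000, 10000, 0.0, voltage=300.0, cs=2.7,
                        amplitude_contrast=0.0)
        n, pixel = 128, 1.0
        lam = fm.electron_wavelength(300.0)

        def chi(k):
            return (np.pi * lam * 10000 * k ** 2
                    - 0.5 * np.pi * 2.7e7 * lam ** 3 * k ** 4)

        k_zero = brentq(lambda k: chi(k) - np.pi, 1e-4, 0.2)
        arr = fm.ctf_evaluate(ctf, n, pixel)
        profile = arr[0, 1: n // 2]  # kx axis; skip the exact zero at DC
        sign_change = np.where(np.diff(np.sign(profile)))[0]
        k_first = (sign_change[0] + 1) / (n * pixel)
        assert abs(k_first - k_zero) <= 1.0 / (n * pixel)


class TestProjectPoints:
    def test_identity_pose(self, rng):
        c = rng.normal(size=(5, 3))
        xi = fm.project_points(c, (0.0, 0.0, 0.0))
        assert np.allclose(xi, c[:, :2])

    def test_rotation_about_z(self, rng):
        c = rng.normal(size=(5, 3))
        xi = fm.project_points(c, (90.0, 0.0, 0.0))
        expected = np.stack([-c[:, 1], c[:, 0]], axis=1)
        assert np.allclose(xi, expected, atol=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10 ** 6),
           rot=st.floats(-180, 180), tilt=st.floats(0, 180),
           psi=st.floats(-180, 180))
    def test_projection_contracts_distances(self, seed, rot, tilt, psi):
        """Rigid projection never increases pairwise distances."""
        rng = np.random.default_rng(seed)
        c = rng.normal(size=(10, 3)) * 20
        xi = fm.project_points(c, (rot, tilt, psi), rng.uniform(-5, 5, 2))
        d3 = np.linalg.norm(c[:, None] - c[None], axis=-1)
        d2 = np.linalg.norm(xi[:, None] - xi[None], axis=-1)
        assert np.all(d2 <= d3 + 1e-9)


class TestSplatAndFilter:
    def test_centered_gaussian_real_and_symmetric(self):
        model = GaussianModel([[0.0, 0.0, 0.0]], [4.0], [1.0],
                              np.ones((1, 1)))
        pts = np.zeros((1, 1, 2))
        g = fm.splat_and_filter(pts, model, np.ones((32, 32)), 32, 2.0).data[0]
        mag = np.abs(g)
        # radially symmetric magnitude (around DC, Nyquist row dropped),
        # zero phase for a point at the origin
        sh = np.fft.fftshift(mag)[1:, 1:]
        assert np.abs(sh - np.rot90(sh)).max() < 1e-6 * mag.max()
        assert np.abs(np.angle(g[:8, :8])).max() < 1e-3

    def test_fourier_shift_theorem_exact_on_subpixel_grid(self, small_model):
        """Shifts that are integer multiples of the splat sub-pixel obey
        the shift theorem to machine precision (bilinear splat is exact
        on its own grid)."""
        n, pixel = 32, 2.0
        pts = small_model.centers[:, :2][None]
        ctf = np.ones((n, n))
        g0 = fm.splat_and_filter(pts, small_model, ctf, n, pixel).data[0]
        t = np.array([3.0, -2.0])  # multiples of pixel/oversample = 1 A
        g1 = fm.splat_and_filter(pts + t, small_model, ctf, n, pixel).data[0]
        f = np.fft.fftfreq(n, d=pixel)
        ky, kx = np.meshgrid(f, f, indexing="ij")
        pred = g0 * np.exp(-2j * np.pi * (kx * t[0] + ky * t[1]))
        assert np.abs(g1 - pred).max() < 1e-12 * np.abs(g0).max()

    def test_fourier_shift_theorem_off_grid(self, small_model):
        """Off-grid shifts agree up to the bilinear interpolation error,
        which shrinks with the oversampling factor."""
        n, pixel = 32, 2.0
        pts = small_model.centers[:, :2][None]
        ctf = np.ones((n, n))
        t = np.array([1.37, -0.83])
        f = np.fft.fftfreq(n, d=pixel)
        ky, kx = np.meshgrid(f, f, indexing="ij")
        phase = np.exp(-2j * np.pi * (kx * t[0] + ky * t[1]))
        errs = {}
        for ovs in (2, 4):
            g0 = fm.splat_and_filter(pts, small_model, ctf, n, pixel,
                                     oversample=ovs).data[0]
            g1 = fm.splat_and_filter(pts + t, small_model, ctf, n, pixel,
                                     oversample=ovs).data[0]
            errs[ovs] = np.abs(g1 - g0 * phase).max() / np.abs(g0).max()
        assert errs[2] < 0.02
        assert errs[4] < 0.5 * errs[2]

    def test_matches_real_space_projection_oracle(self, rng):
        """Fourier path vs render -> rotate -> sum -> FFT -> CTF oracle."""
        n, pixel = 32, 2.0
        centers = rng.uniform(-18, 18, size=(8, 3))
        model = GaussianModel(centers, [4.0], [1.5], np.ones((1, 8)))
        euler = (25.0, 40.0, -30.0)
        ctf = fm.ctf_evaluate(CTFParams(12000, 14000, 20.0), n, pixel)
        pts = fm.project_points(centers, euler)
        g = fm.splat_and_filter(pts[None], model, ctf, n, pixel).data[0]
        rot = fm.rotation_matrix(*euler)
        rotated = GaussianModel(centers @ rot.T, model.widths,
                                model.amplitudes, model.class_weights)
        proj = render_density(rotated, (n, pixel)).data.sum(axis=0) * pixel
        oracle = np.fft.fft2(np.fft.ifftshift(proj), norm="ortho") * ctf
        ncc = np.abs(np.vdot(oracle, g)) / (np.linalg.norm(oracle)
                                            * np.linalg.norm(g))
        assert ncc > 0.99

    def test_all_points_out_of_bounds_rejected(self, small_model):
        pts = np.full((1, 8, 2), 1e5)
        with pytest.raises(ValueError):
            fm.splat_and_filter(pts, small_model, np.ones((32, 32)), 32, 2.0)

    def test_pose_equivariance(self, rng):
        """Rotating the model and un-rotating the pose gives the same image."""
        n, pixel = 32, 2.0
        centers = rng.uniform(-15, 15, size=(6, 3))
        model = GaussianModel(centers, [4.0], [1.0], np.ones((1, 6)))
        ctf = np.ones((n, n))
        e1 = (30.0, 50.0, -20.0)
        r_extra = fm.rotation_matrix(40.0, 0.0, 0.0)
        # model rotated by r_extra, pose composed with inverse rotation
        rot_model = GaussianModel(centers @ r_extra.T, model.widths,
                                  model.amplitudes, model.class_weights)
        r_total = fm.rotation_matrix(*e1)
        pts_a = centers @ r_total[:2].T
        pts_b = (centers @ r_extra.T) @ (r_total @ r_extra.T)[:2].T
        ga = fm.splat_and_filter(pts_a[None], model, ctf, n, pixel).data
        gb = fm.splat_and_filter(pts_b[None], rot_model, ctf, n, pixel).data
        assert np.allclose(ga, gb, atol=1e-6 * np.abs(ga).max())

    def test_energy_conservation(self):
        """With CTF=1, the image integral equals the Gaussian mass."""
        n, pixel = 48, 2.0
        model = GaussianModel([[1.0, -2.0, 3.0]], [4.0], [1.3],
                              np.ones((1, 1)))
        g = fm.splat_and_filter(model.centers[:, :2][None], model,
                                np.ones((n, n)), n, pixel).data[0]
        img = np.fft.ifft2(g, norm="ortho").real
        total = img.sum() * pixel ** 2
        expected = 1.3 * np.pi ** 1.5 * 4.0 ** 3  # integral of the Gaussian
        assert total == pytest.approx(expected, rel=1e-3)


def _stack_from_projections(model, n_particles, n, pixel, rng, noise=0.0):
    eulers = np.stack([rng.uniform(0, 360, n_particles),
                       np.rad2deg(np.arccos(rng.uniform(-1, 1, n_particles))),
                       rng.uniform(0, 360, n_particles)], axis=1)
    shifts = rng.uniform(-2, 2, size=(n_particles, 2))
    ctfs = [CTFParams(rng.uniform(8000, 25000), rng.uniform(8000, 25000),
                      rng.uniform(0, 180)) for _ in range(n_particles)]
    images = np.zeros((n_particles, n, n), dtype=np.float32)
    stack = ParticleStack(images, pixel, eulers, shifts, ctfs,
                          np.arange(n_particles) % 2 + 1)
    g = fm.model_projections(stack, model, np.arange(n_particles))
    clean = fm.real_image(fm.FourierImage(g, pixel))
    stack.images[:] = clean + noise * rng.standard_normal(clean.shape)
    return stack


class TestNoiseSpectrum:
    def test_zero_noise_gives_floor(self, small_model, rng):
        stack = _stack_from_projections(small_model, 8, 32, 2.0, rng)
        noise = fm.estimate_noise_spectrum(stack, small_model,
                                           subset=np.arange(8))
        floor = noise.weights.min()
        assert np.allclose(noise.weights, floor, rtol=1e-6)

    def test_white_noise_level_recovered(self, small_model, rng):
        v = 0.7
        stack = _stack_from_projections(small_model, 256, 32, 2.0, rng,
                                        noise=np.sqrt(v))
        noise = fm.estimate_noise_spectrum(stack, small_model,
                                           subset=np.arange(256))
        # shell 0 holds a single chi-square(1) coefficient: wide bound
        assert 0.5 * v <= noise.weights[0] <= 1.5 * v
        assert np.all(noise.weights[1:] >= 0.8 * v)
        assert np.all(noise.weights[1:] <= 1.2 * v)

    def test_invariant_to_particle_order(self, small_model, rng):
        stack = _stack_from_projections(small_model, 16, 32, 2.0, rng,
                                        noise=0.5)
        n1 = fm.estimate_noise_spectrum(stack, small_model,
                                        subset=np.arange(16))
        n2 = fm.estimate_noise_spectrum(stack, small_model,
                                        subset=np.arange(16)[::-1])
        assert np.allclose(n1.weights, n2.weights)


class TestDataLoss:
    def test_zero_when_equal(self, rng):
        g = rng.normal(size=(3, 16, 16)) + 1j * rng.normal(size=(3, 16, 16))
        noise = fm.NoiseModel(np.ones(9), 16, 2.0)
        assert fm.data_loss(g, g, noise) == 0.0

    def test_batch_duplication_invariant(self, rng):
        g = rng.normal(size=(2, 16, 16)) + 0j
        y = rng.normal(size=(2, 16, 16)) + 0j
        noise = fm.NoiseModel(np.full(9, 2.0), 16, 2.0)
        l1 = fm.data_loss(g, y, noise)
        l2 = fm.data_loss(np.tile(g, (2, 1, 1)), np.tile(y, (2, 1, 1)), noise)
        assert l1 == pytest.approx(l2)

    def test_parseval_identity_with_unit_sigma(self, rng):
        """With Sigma=1 the Fourier loss equals the real-space sum of
        squares (orthonormal FFT)."""
        a = rng.normal(size=(1, 16, 16))
        b = rng.normal(size=(1, 16, 16))
        ga = np.fft.fft2(a, norm="ortho")
        gb = np.fft.fft2(b, norm="ortho")
        noise = fm.NoiseModel(np.ones(9), 16, 2.0)
        assert fm.data_loss(ga, gb, noise) == pytest.approx(
            np.sum((a - b) ** 2))


class TestDifferentiability:
    def test_gradient_matches_finite_differences(self, small_model, rng):
        """Data-loss gradient wrt projected points vs finite differences."""
        n, pixel = 32, 2.0
        pts = small_model.centers[:, :2][None].copy()
        ctf = fm.ctf_evaluate(CTFParams(12000, 12000, 0.0), n, pixel)[None]
        y = fm.splat_and_filter(pts + 0.5, small_model, ctf[0], n,
                                pixel).data
        sig = np.ones((n, n))
        t = ad.Tensor(pts, requires_grad=True)
        loss = fm.projection_loss(
            t, ad.Tensor(small_model.class_weights),
            ad.Tensor(small_model.amplitudes),
            ad.Tensor(small_model.widths), y, ctf, sig, n, pixel)
        loss.backward()

        def f(p):
            g, _ = fm._form_images(p, small_model.class_weights,
                                   small_model.amplitudes,
                                   small_model.widths, ctf, n, pixel)
            return float(np.sum(np.abs(g - y) ** 2 / sig))

        eps = 1e-4
        for flat in rng.choice(pts.size, 5, replace=False):
            p1, p2 = pts.copy(), pts.copy()
            p1.flat[flat] += eps
            p2.flat[flat] -= eps
            num = (f(p1) - f(p2)) / (2 * eps)
            assert t.grad.flat[flat] == pytest.approx(num, rel=1e-4, abs=1e-9)
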