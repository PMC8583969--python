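"""Restoration functional, gradient, and solver behavior."""

import warnings

import numpy as np
import pytest

from tdeconv import (
    ImageStack,
    PSF,
    RestorationParams,
    evaluate_functional,
    evaluate_gradient,
    make_gaussian_psf,
    solve,
)
from tdeconv.operators import apply_psf


def brute_force_cost(v, w, kernel, lam, lam_t, lam_n, eps):
    """Term-by-term evaluation of the cost with explicit modular-index loops."""
    t_, ny, nx = v.shape

    def conv(arr, k, axes):
        kshape = [1, 1, 1]
        for ax, n in zip(axes, k.shape):
            kshape[ax] = n
        k3 = k.reshape(kshape)
        out = np.zeros_like(arr)
        centers = [s // 2 for s in k3.shape]
        for idx in np.ndindex(arr.shape):
            s = 0.0
            for kidx in np.ndindex(k3.shape):
                src = tuple(
                    (idx[d] - (kidx[d] - centers[d])) % arr.shape[d]
                    for d in range(3)
                )
                s += k3[kidx] * arr[src]
            out[idx] = s
        return out

    d2 = np.array([1.0, -2.0, 1.0])
    d1 = np.array([-0.5, 0.0, 0.5])
    spatial = [(d2, (2,)), (d2, (1,)), (np.outer(d1, d1), (1, 2))]
    temporal = [(d2, (0,)), (np.outer(d1, d1), (0, 2)), (np.outer(d1, d1), (0, 1))]

    hv = conv(v, kernel, (1, 2))
    cost = float(((hv - w) ** 2).sum())

    g = v * v + eps
    for k, axes in spatial:
        g = g + conv(v, k, axes) ** 2
    cost += lam * float(np.log(g).sum())

    g = v * v + eps
    for k, axes in temporal:
        g = g + conv(v, k, axes) ** 2
    cost += lam_t * float(np.log(g).sum())

    neg = v[v < 0]
    cost += lam_n * float(np.sum(-(neg**3)))
    return cost


def test_cost_of_zero_stack_is_2k_log_eps():
    """All quadratic and derivative terms vanish on the zero stack."""
    z = np.zeros((3, 4, 4))
    psf = make_gaussian_psf(1.0, 3)
    params = RestorationParams(
        lambda_spatial=1.0, lambda_temporal=1.0, lambda_nonneg=5.0, epsilon=1e-3
    )
    k = z.size
    np.testing.assert_allclose(
        evaluate_functional(z, z, psf, params), 2 * k * np.log(1e-3), rtol=1e-12
    )


def test_pure_data_term_zero_at_exact_fit(rng):
    v = ImageStack(rng.random((3, 8, 8)))
    psf = make_gaussian_psf(1.2, 5)
    w = apply_psf(v, psf)
    params = RestorationParams(
        lambda_spatial=0.0, lambda_temporal=0.0, lambda_nonneg=0.0
    )
    assert evaluate_functional(v, w, psf, params) <= 1e-18
    np.testing.assert_allclose(
        evaluate_gradient(v, w, psf, params), 0.0, atol=1e-12
    )


def test_cost_matches_brute_force_oracle(rng):
    v = rng.normal(0.2, 0.5, (3, 4, 4))
    w = rng.normal(0.2, 0.5, (3, 4, 4))
    kern = rng.random((3, 3))
    psf = PSF(kern)
    lam, lam_t, lam_n, eps = 0.7, 0.4, 2.0, 1e-2
    params = RestorationParams(
        lambda_spatial=lam, lambda_temporal=lam_t, lambda_nonneg=lam_n, epsilon=eps
    )
    expected = brute_force_cost(v, w, psf.kernel, lam, lam_t, lam_n, eps)
    np.testing.assert_allclose(
        evaluate_functional(v, w, psf, params), expected, rtol=1e-10
    )


def test_gradient_matches_finite_differences(rng):
    """Central finite differences of the cost, >= 20 random small instances."""
    psf = make_gaussian_psf(1.0, 5)
    h = 1e-6
    for i in range(20):
        params = RestorationParams(
            lambda_spatial=rng.uniform(0.05, 0.5),
            lambda_temporal=rng.uniform(0.05, 0.5),
            lambda_nonneg=rng.uniform(0.1, 2.0),
            epsilon=10 ** rng.uniform(-3, -1),
        )
        v = rng.normal(0.3, 0.5, (3, 5, 5))
        w = rng.normal(0.3, 0.5, (3, 5, 5))
        grad = evaluate_gradient(v, w, psf, params)
        fd = np.zeros_like(v)
        for idx in np.ndindex(v.shape):
            vp, vm = v.copy(), v.copy()
            vp[idx] += h
            vm[idx] -= h
            fd[idx] = (
                evaluate_functional(vp, w, psf, params)
                - evaluate_functional(vm, w, psf, params)
            ) / (2 * h)
        scale = np.abs(fd) + 1e-6
        assert np.max(np.abs(grad - fd) / scale) <= 1e-4, f"instance {i}"


def test_gradient_mirror_symmetric(rng):
    """x-mirror symmetric input and PSF give an x-mirror symmetric gradient."""
    psf = make_gaussian_psf(1.0, 5)
    half = rng.random((3, 6, 4))
    v = np.concatenate([half, half[:, :, ::-1]], axis=2)
    w = np.concatenate([half * 0.5, half[:, :, ::-1] * 0.5], axis=2)
    params = RestorationParams(lambda_nonneg=1.0)
    g = evaluate_gradient(v, w, psf, params)
    np.testing.assert_allclose(g, g[:, :, ::-1], atol=1e-10)


def test_epsilon_guard_rejected():
    with pytest.raises(ValueError, match="epsilon"):
        RestorationParams(epsilon=0.0)


def test_shape_mismatch_rejected(rng):
    psf = make_gaussian_psf(1.0, 3)
    with pytest.raises(ValueError, match="shapes differ"):
        evaluate_functional(rng.random((2, 5, 5)), rng.random((3, 5, 5)), psf,
                            RestorationParams())


# -- solver -------------------------------------------------------------------


def test_solver_near_identity_problem(rng):
    """Delta PSF, no noise, negligible regularization: vopt recovers w."""
    delta = np.zeros((3, 3))
    delta[1, 1] = 1.0
    w = ImageStack(rng.random((4, 12, 12)))
    params = RestorationParams(
        lambda_spatial=1e-6, lambda_temporal=1e-6, lambda_nonneg=0.0,
        max_iter=200, tol=1e-12,
    )
    res = solve(w, PSF(delta), params)
    drange = w.dynamic_range()
    assert np.max(np.abs(res.vopt.data - w.data)) <= 0.01 * drange


def test_solver_trace_non_increasing(tiny_scene):
    res = solve(
        tiny_scene["noisy"], tiny_scene["psf"],
        RestorationParams(max_iter=30, tol=1e-8),
    )
    trace = np.asarray(res.trace)
    assert np.all(np.diff(trace) <= 0)
    assert len(trace) >= 2


def test_solver_output_non_negative(tiny_scene):
    res = solve(
        tiny_scene["noisy"], tiny_scene["psf"],
        RestorationParams(max_iter=20, tol=1e-6),
    )
    assert res.vopt.data.min() >= 0
    assert 0 <= res.clipped_fraction <= 1


def test_static_limit_decouples_frames(rng):
    """lambda_T = 0: the stack solve equals independent per-frame solves."""
    frames = []
    for t in range(4):
        f = np.zeros((16, 16))
        f[4 + t, 5] = 1.0
        f[10, 3 + t] = 0.8
        frames.append(f)
    clean = ImageStack(np.stack(frames))
    psf = make_gaussian_psf(1.2, 7)
    w = apply_psf(clean, psf)
    w = w.copy_with(w.data + 0.05 * rng.normal(size=w.shape))
    params = RestorationParams(
        lambda_spatial=0.05, lambda_temporal=0.0, lambda_nonneg=1.0,
        epsilon=1e-3, max_iter=500, tol=1e-13,
    )
    res_stack = solve(w, psf, params, normalize=False)
    per_frame = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # T=1 static fallback
        for t in range(4):
            res_t = solve(
                ImageStack(w.data[t][np.newaxis]), psf, params, normalize=False
            )
            per_frame.append(res_t.vopt.data[0])
    diff = np.max(np.abs(res_stack.vopt.data - np.stack(per_frame)))
    assert diff <= 1e-3 * w.dynamic_range()


def test_solver_shift_equivariant(tiny_scene):
    """Cyclic shift of the data cyclically shifts the restored stack."""
    w = tiny_scene["noisy"]
    psf = tiny_scene["psf"]
    params = RestorationParams(max_iter=15, tol=1e-8)
    shift = (2, 5, 3)
    res = solve(w, psf, params)
    res_shifted = solve(w.copy_with(np.roll(w.data, shift, axis=(0, 1, 2))),
                        psf, params)
    np.testing.assert_allclose(
        res_shifted.vopt.data,
        np.roll(res.vopt.data, shift, axis=(0, 1, 2)),
        atol=1e-6 * w.dynamic_range(),
    )


def test_stronger_spatial_weight_smooths_more(tiny_scene):
    """Doubling lambda weakly decreases the (unweighted) spatial penalty of
    the minimizer and weakly increases its data misfit — the variational
    trade-off of the regularization weight."""
    w = tiny_scene["noisy"]
    psf = tiny_scene["psf"]

    def terms(lam):
        params = RestorationParams(
            lambda_spatial=lam, lambda_temporal=0.0, lambda_nonneg=1.0,
            max_iter=200, tol=1e-10,
        )
        res = solve(w, psf, params, normalize=False)
        v = res.vopt.data
        data = evaluate_functional(
            v, w, psf,
            RestorationParams(lambda_spatial=0.0, lambda_temporal=0.0,
                              lambda_nonneg=0.0),
        )
        with_spatial = evaluate_functional(
            v, w, psf,
            RestorationParams(lambda_spatial=1.0, lambda_temporal=0.0,
                              lambda_nonneg=0.0),
        )
        return data, with_spatial - data  # (misfit, unweighted spatial penalty)

    d1, s1 = terms(0.05)
    d2, s2 = terms(0.10)
    assert s2 <= s1 + 1e-6 * abs(s1)
    assert d2 >= d1 - 1e-6 * abs(d1)


def test_two_frame_stack_warns_and_uses_static_path(rng):
    w = ImageStack(rng.random((2, 8, 8)))
    psf = make_gaussian_psf(1.0, 3)
    with pytest.warns(UserWarning):
        res = solve(w, psf, RestorationParams(max_iter=5))
    assert res.vopt.shape == w.shape


def test_time_padding_preserves_shape(tiny_scene):
    res = solve(
        tiny_scene["noisy"], tiny_scene["psf"],
        RestorationParams(max_iter=5), time_pad=2,
    )
    assert res.vopt.shape == tiny_scene["noisy"].shape
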