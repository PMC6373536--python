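"""First-passage sampling for the two-boundary Wiener diffusion process.

The decision process is ``dX = v dt + s dW`` started at ``z = a/2`` and
absorbed at 0 (error) or ``a`` (correct, for v > 0). Sampling uses
Euler-Maruyama with a Brownian-bridge within-step crossing correction:
after each step that leaves the path inside (0, a), the path is absorbed
with the exact bridge probability of having touched a boundary during the
step, ``exp(-2 (a - x_t)(a - x_{t+dt}) / (s^2 dt))`` for the upper boundary
(mirror for the lower). This removes the O(sqrt(dt)) boundary-overshoot
bias of the plain Euler scheme, leaving an O(dt) discretisation error that
is negligible against Monte-Carlo noise at the sample sizes used here.
"""

from __future__ import annotations

import numpy as np

from .types import DiffusionParams

__all__ = ["simulate_rts", "simulate_first_passage"]


def simulate_first_passage(
    v,
    a,
    ter,
    *,
    s: float = 1.0,
    n_trials: int | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 5e-4,
    max_time: float = 20.0,
):
    """Vectorised first-passage sampler; parameters may vary per trial.

    Parameters
    ----------
    v, a, ter : array_like
        Drift, boundary separation and non-decision time (s), broadcast
        to a common trial count. ``n_trials`` may be given instead when
        all three are scalars.
    s : float
        Diffusion noise scaling.
    rng : numpy.random.Generator
        Source of randomness (required for reproducibility; a fresh
        generator is created when omitted).
    dt : float
        Euler step in seconds.
    max_time : float
        Decision-time cap; paths still alive are absorbed at the
        drift-favoured boundary (practically unreachable for the
        parameter ranges used here).

    Returns
    -------
    rt_s : ndarray
        Response times in seconds, ``ter`` included.
    hit_upper : ndarray of bool
        True where the path was absorbed at the upper boundary.
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    ter = np.asarray(ter, dtype=float)
    if n_trials is not None:
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        shape = (int(n_trials),)
    else:
        shape = np.broadcast_shapes(v.shape, a.shape, ter.shape)
        if shape == ():
            shape = (1,)
    v = np.broadcast_to(v, shape).astype(float).ravel()
    a = np.broadcast_to(a, shape).astype(float).ravel()
    ter = np.broadcast_to(ter, shape).astype(float).ravel()
    n = v.size

    if np.any(a <= 0):
        raise ValueError("boundary separation a must be positive")
    if s <= 0:
        raise ValueError("noise scaling s must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng()

    x = a / 2.0
    decision_t = np.empty(n)
    hit_upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sdt = s * np.sqrt(dt)
    var_dt = s * s * dt
    max_steps = int(np.ceil(max_time / dt))

    step = 0
    while active.size and step < max_steps:
        step += 1
        xa = x[active]
        aa = a[active]
        xn = xa + v[active] * dt + sdt * rng.standard_normal(active.size)

        up = xn >= aa
        dn = xn <= 0.0
        inside = ~(up | dn)
        if inside.any():
            # bridge probability of an unobserved within-step crossing
            xi, xni, ai = xa[inside], xn[inside], aa[inside]
            p_up = np.exp(-2.0 * (ai - xi) * (ai - xni) / var_dt)
            p_dn = np.exp(-2.0 * xi * xni / var_dt)
            u = rng.random(xi.size)
            bridged_up = u < p_up
            bridged_dn = (~bridged_up) & (u < p_up + p_dn)
            idx = np.flatnonzero(inside)
            up[idx[bridged_up]] = True
            dn[idx[bridged_dn]] = True

        done = up | dn
        finished = active[done]
        decision_t[finished] = step * dt
        hit_upper[finished] = up[done]
        x[active[~done]] = xn[~done]
        active = active[~done]

    if active.size:  # pragma: no cover - unreachable for sane parameters
        decision_t[active] = max_time
        hit_upper[active] = v[active] > 0

    return (ter + decision_t).reshape(shape), hit_upper.reshape(shape)


def simulate_rts(
    params: DiffusionParams,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    dt: float = 5e-4,
) -> list[tuple[float, bool]]:
    """Simulate ``n_trials`` decisions under a single parameter set.

    Returns a list of ``(rt_ms, hit_upper)`` pairs; ``hit_upper`` marks
    absorption at the boundary favoured by positive drift, i.e. the
    correct response for v > 0.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rt_s, upper = simulate_first_passage(
        params.v, params.a, params.ter, s=params.s, n_trials=n_trials, rng=rng, dt=dt
    )
    return list(zip((rt_s * 1000.0).tolist(), upper.tolist()))
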