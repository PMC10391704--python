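"""Independent reference implementations used only by the test suite.

These deliberately avoid the production code paths: the shelled-sphere
oracle solves the electrostatic boundary-value problem directly, and the
template-fit oracle is a multi-resolution grid search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

EPS0 = 8.8541878128e-12


def shelled_sphere_bvp(
    radius_um: float,
    thickness_nm: float,
    sigma_mem: float,
    eps_mem: float,
    sigma_cyt: float,
    eps_cyt: float,
    frequency: float,
) -> complex:
    """Equivalent permittivity of a shelled sphere from first principles.

    Solves Laplace's equation for a core/shell/medium geometry in a uniform
    applied field with the dipole ansatz

        phi_med  = (-r + B / r^2) cos(theta)
        phi_shell = (-C r + D / r^2) cos(theta)
        phi_core = -E r cos(theta)

    imposing continuity of potential and of the normal complex current
    density (eps* weighted flux) at both interfaces, then inverts the
    homogeneous-sphere dipole relation f = (eps_eq - eps_1)/(eps_eq + 2 eps_1)
    for eps_eq.  The reference medium (vacuum) is arbitrary: the equivalent
    permittivity is a property of the particle alone.
    """
    w = 2.0 * np.pi * frequency
    e1 = EPS0 + 0j  # reference medium: vacuum
    e2 = EPS0 * eps_mem - 1j * sigma_mem / w
    e3 = EPS0 * eps_cyt - 1j * sigma_cyt / w
    r1 = radius_um
    r2 = radius_um - thickness_nm * 1e-3

    # unknowns: B, C, D, E
    m = np.array(
        [
            [1.0 / r1**2, r1, -1.0 / r1**2, 0.0],
            [-2.0 * e1 / r1**3, e2, 2.0 * e2 / r1**3, 0.0],
            [0.0, -r2, 1.0 / r2**2, r2],
            [0.0, -e2, -2.0 * e2 / r2**3, e3],
        ],
        dtype=complex,
    )
    rhs = np.array([r1, e1, 0.0, 0.0], dtype=complex)
    b, c, d, e = np.linalg.solve(m, rhs)
    f_cm = b / r1**3
    return e1 * (1.0 + 2.0 * f_cm) / (1.0 - f_cm)


def _grid_costs(window, t, tcs, seps, sigs):
    """Evaluate the projection cost at every grid point; yield all results."""
    out = []
    for tc in tcs:
        for sep in seps:
            t1, t2 = tc - sep / 2, tc + sep / 2
            for sig in sigs:
                basis = np.exp(-0.5 * ((t - t1) / sig) ** 2) - np.exp(
                    -0.5 * ((t - t2) / sig) ** 2
                )
                bb = basis @ basis
                if bb <= 0:
                    continue
                amps = (window @ basis) / bb
                resid = window - amps[:, None] * basis[None, :]
                cost = float(np.sum(np.abs(resid) ** 2))
                out.append((cost, amps, (tc, sep, sig)))
    return out


def grid_search_bipolar_fit(
    window: np.ndarray,
    t: np.ndarray,
    n_grid: int = 21,
    n_refine: int = 15,
    n_levels: int = 3,
    n_basins: int = 8,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Brute-force bipolar-Gaussian fit by multi-resolution grid search.

    Searches (center, lobe separation, lobe sigma): a coarse global grid
    (log-spaced in sigma) followed by independent refinement of the best
    mutually distinct coarse basins, so a degenerate coarse optimum (e.g. a
    single-lobe solution with one lobe outside the window) cannot hide the
    true one; the winning basin is finally polished by a derivative-free
    simplex on the same scalar cost (the valley is curved and flat, which
    axis-aligned shrinking grids cannot walk to the floor of).  At every
    evaluated point the per-channel complex amplitude is the exact linear
    least-squares solution.  Returns (amplitudes per channel, (t1, t2,
    sigma)) of the best point found.
    """
    window = np.atleast_2d(np.asarray(window, dtype=complex))
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    span = t[-1] - t[0]

    coarse = _grid_costs(
        window,
        t,
        np.linspace(t[0], t[-1], n_grid),
        np.linspace(2 * dt, span, n_grid),
        np.geomspace(dt / 2, span / 2, n_grid),
    )
    coarse.sort(key=lambda c: c[0])
    tc_step = span / (n_grid - 1)
    sep_step = (span - 2 * dt) / (n_grid - 1)

    # pick the best few mutually distinct basins
    basins = []
    for cost, amps, p in coarse:
        if all(
            abs(p[0] - q[0]) > 2 * tc_step or abs(p[1] - q[1]) > 2 * sep_step
            for _, _, q in basins
        ) or not basins:
            if not basins or (
                abs(p[0] - basins[0][2][0]) > 0 or abs(p[1] - basins[0][2][1]) > 0
            ):
                basins.append((cost, amps, p))
        if len(basins) >= n_basins:
            break

    best = min(basins, key=lambda c: c[0])
    for _, _, (tc_b, sep_b, sig_b) in basins:
        tc_w, sep_w = 2 * tc_step, 2 * sep_step
        sig_lo, sig_hi = sig_b / 2.5, sig_b * 2.5
        tc_lo, tc_hi = tc_b - tc_w, tc_b + tc_w
        sep_lo, sep_hi = max(2 * dt, sep_b - sep_w), sep_b + sep_w
        for _ in range(n_levels):
            level = _grid_costs(
                window,
                t,
                np.linspace(tc_lo, tc_hi, n_refine),
                np.linspace(sep_lo, sep_hi, n_refine),
                np.linspace(sig_lo, sig_hi, n_refine),
            )
            local = min(level, key=lambda c: c[0])
            if local[0] < best[0]:
                best = local
            tc_b, sep_b, sig_b = local[2]
            tc_w = (tc_hi - tc_lo) / (n_refine - 1) * 2.0
            sep_w = (sep_hi - sep_lo) / (n_refine - 1) * 2.0
            sig_w = (sig_hi - sig_lo) / (n_refine - 1) * 2.0
            tc_lo, tc_hi = tc_b - tc_w, tc_b + tc_w
            sep_lo, sep_hi = max(2 * dt, sep_b - sep_w), sep_b + sep_w
            sig_lo, sig_hi = max(dt / 4, sig_b - sig_w), sig_b + sig_w

    def scalar_cost(p):
        got = _grid_costs(window, t, [p[0]], [abs(p[1])], [abs(p[2])])
        return got[0][0] if got else np.inf

    cost, amps, (tc, sep, sig) = best
    polish = minimize(
        scalar_cost,
        np.array([tc, sep, sig]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if polish.fun < cost:
        tc, sep, sig = polish.x[0], abs(polish.x[1]), abs(polish.x[2])
        _, amps, _ = _grid_costs(window, t, [tc], [sep], [sig])[0]
    return np.asarray(amps), (tc - sep / 2, tc + sep / 2, sig)
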