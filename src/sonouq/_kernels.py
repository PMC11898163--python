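"""Numba time-stepping kernels for the lossy acoustic wave solver.

One leapfrog update of the damped heterogeneous-density wave equation

    (1/c^2) d2p/dt2 + (Gamma/c^2) dp/dt = rho div( (1/rho) grad p )

discretised with second-order central differences on a collocated grid,
face buoyancy 0.5*(1/rho_i + 1/rho_nb), and damping treated semi-implicitly
(centered dp/dt), which keeps the scheme stable for arbitrarily large
sponge damping. Precomputed per-voxel arrays:

    binv   = 1 / rho
    lam    = 0.5 * rho * c^2 * dt^2 / dx^2
    g      = 0.5 * Gamma * dt                (Gamma = 2*alpha*c + sponge)
    inv1pg = 1 / (1 + g)

Source voxels are hard (Dirichlet): overwritten with ``sval`` after the
update. The ``accumulate`` kernels add the squared updated pressure into a
float64 buffer during the recording window (RMS amplitude extraction); they
are kept separate from the stepping kernels so the hot loop stays
branch-free and vectorizable.
"""

import numba
import numpy as np

_SIG_OPTS = dict(cache=True, fastmath=True, boundscheck=False)


@numba.njit(**_SIG_OPTS)
def step_1d(p_old, p, p_new, binv, lam, g, inv1pg, si, sval, additive):
    n = p.shape[0]
    for i in range(1, n - 1):
        bc = binv[i]
        lap = (binv[i + 1] + bc) * (p[i + 1] - p[i]) - (bc + binv[i - 1]) * (
            p[i] - p[i - 1]
        )
        p_new[i] = (
            2.0 * p[i] - p_old[i] + lam[i] * lap + g[i] * p_old[i]
        ) * inv1pg[i]
    for s in range(si.shape[0]):
        if additive:
            p_new[si[s]] += sval[s]
        else:
            p_new[si[s]] = sval[s]


@numba.njit(**_SIG_OPTS)
def step_2d(p_old, p, p_new, binv, lam, g, inv1pg, si, sj, sval, additive):
    nx, ny = p.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            bc = binv[i, j]
            lap = (
                (binv[i + 1, j] + bc) * (p[i + 1, j] - p[i, j])
                - (bc + binv[i - 1, j]) * (p[i, j] - p[i - 1, j])
                + (binv[i, j + 1] + bc) * (p[i, j + 1] - p[i, j])
                - (bc + binv[i, j - 1]) * (p[i, j] - p[i, j - 1])
            )
            p_new[i, j] = (
                2.0 * p[i, j] - p_old[i, j] + lam[i, j] * lap + g[i, j] * p_old[i, j]
            ) * inv1pg[i, j]
    for s in range(si.shape[0]):
        if additive:
            p_new[si[s], sj[s]] += sval[s]
        else:
            p_new[si[s], sj[s]] = sval[s]


@numba.njit(**_SIG_OPTS)
def step_3d(p_old, p, p_new, binv, lam, g, inv1pg, si, sj, sk, sval, additive):
    nx, ny, nz = p.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                bc = binv[i, j, k]
                lap = (
                    (binv[i + 1, j, k] + bc) * (p[i + 1, j, k] - p[i, j, k])
                    - (bc + binv[i - 1, j, k]) * (p[i, j, k] - p[i - 1, j, k])
                    + (binv[i, j + 1, k] + bc) * (p[i, j + 1, k] - p[i, j, k])
                    - (bc + binv[i, j - 1, k]) * (p[i, j, k] - p[i, j - 1, k])
                    + (binv[i, j, k + 1] + bc) * (p[i, j, k + 1] - p[i, j, k])
                    - (bc + binv[i, j, k - 1]) * (p[i, j, k] - p[i, j, k - 1])
                )
                p_new[i, j, k] = (
                    2.0 * p[i, j, k]
                    - p_old[i, j, k]
                    + lam[i, j, k] * lap
                    + g[i, j, k] * p_old[i, j, k]
                ) * inv1pg[i, j, k]
    for s in range(si.shape[0]):
        if additive:
            p_new[si[s], sj[s], sk[s]] += sval[s]
        else:
            p_new[si[s], sj[s], sk[s]] = sval[s]


@numba.njit(**_SIG_OPTS)
def accumulate_sq(acc, p_new):
    flat_acc = acc.reshape(-1)
    flat_p = p_new.reshape(-1)
    for i in range(flat_p.shape[0]):
        v = flat_p[i]
        flat_acc[i] += v * v
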