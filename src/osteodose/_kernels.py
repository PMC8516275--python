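"""Numba kernels: rod rasterization, point membership, electron stepping.

These are internal hot loops; the public API lives in :mod:`framework`,
:mod:`voxelizer` and :mod:`transport`.  Voxel labels throughout:
0 = void, 1 = cortical bone, 2 = trabecular bone, 3 = marrow.
Material index: 0 = mineralized bone, 1 = marrow.
"""

from __future__ import annotations

import numba
import numpy as np

LBL_VOID = 0
LBL_CORT = 1
LBL_TRAB = 2
LBL_MARROW = 3


@numba.njit(cache=True)
def rasterize_rods(node_pos, node_r, rods, origin, res, mask):
    """Mark voxels whose centre lies inside any conical rod (or end sphere).

    A rod between nodes a, b with end radii ra, rb contains point p iff the
    distance from p to the segment point at the clamped axial projection t is
    within the linearly interpolated radius ra + t*(rb - ra); the clamped ends
    reproduce the junction spheres.
    """
    nx, ny, nz = mask.shape
    for m in range(rods.shape[0]):
        ia = rods[m, 0]
        ib = rods[m, 1]
        ax, ay, az = node_pos[ia, 0], node_pos[ia, 1], node_pos[ia, 2]
        bx, by, bz = node_pos[ib, 0], node_pos[ib, 1], node_pos[ib, 2]
        ra = node_r[ia]
        rb = node_r[ib]
        rmax = max(ra, rb)
        abx, aby, abz = bx - ax, by - ay, bz - az
        ab2 = abx * abx + aby * aby + abz * abz
        lox = min(ax, bx) - rmax
        hix = max(ax, bx) + rmax
        loy = min(ay, by) - rmax
        hiy = max(ay, by) + rmax
        loz = min(az, bz) - rmax
        hiz = max(az, bz) + rmax
        i0 = max(int(np.floor((lox - origin[0]) / res)), 0)
        i1 = min(int(np.floor((hix - origin[0]) / res)) + 1, nx)
        j0 = max(int(np.floor((loy - origin[1]) / res)), 0)
        j1 = min(int(np.floor((hiy - origin[1]) / res)) + 1, ny)
        k0 = max(int(np.floor((loz - origin[2]) / res)), 0)
        k1 = min(int(np.floor((hiz - origin[2]) / res)) + 1, nz)
        for i in range(i0, i1):
            cx = origin[0] + (i + 0.5) * res
            for j in range(j0, j1):
                cy = origin[1] + (j + 0.5) * res
                for k in range(k0, k1):
                    if mask[i, j, k]:
                        continue
                    cz = origin[2] + (k + 0.5) * res
                    if ab2 > 0.0:
                        t = ((cx - ax) * abx + (cy - ay) * aby + (cz - az) * abz) / ab2
                        if t < 0.0:
                            t = 0.0
                        elif t > 1.0:
                            t = 1.0
                    else:
                        t = 0.0
                    px = ax + t * abx
                    py = ay + t * aby
                    pz = az + t * abz
                    rt = ra + t * (rb - ra)
                    dx, dy, dz = cx - px, cy - py, cz - pz
                    if dx * dx + dy * dy + dz * dz <= rt * rt:
                        mask[i, j, k] = 1


@numba.njit(cache=True)
def points_in_bone(node_pos, node_r, rods, pts):
    """Brute-force membership of each point in the rod union (bool array)."""
    n = pts.shape[0]
    out = np.zeros(n, dtype=np.bool_)
    for q in range(n):
        cx, cy, cz = pts[q, 0], pts[q, 1], pts[q, 2]
        for m in range(rods.shape[0]):
            ia = rods[m, 0]
            ib = rods[m, 1]
            ax, ay, az = node_pos[ia, 0], node_pos[ia, 1], node_pos[ia, 2]
            bx, by, bz = node_pos[ib, 0], node_pos[ib, 1], node_pos[ib, 2]
            ra = node_r[ia]
            rb = node_r[ib]
            rmax = max(ra, rb)
            if (
                cx < min(ax, bx) - rmax
                or cx > max(ax, bx) + rmax
                or cy < min(ay, by) - rmax
                or cy > max(ay, by) + rmax
                or cz < min(az, bz) - rmax
                or cz > max(az, bz) + rmax
            ):
                continue
            abx, aby, abz = bx - ax, by - ay, bz - az
            ab2 = abx * abx + aby * aby + abz * abz
            if ab2 > 0.0:
                t = ((cx - ax) * abx + (cy - ay) * aby + (cz - az) * abz) / ab2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
            else:
                t = 0.0
            px = ax + t * abx
            py = ay + t * aby
            pz = az + t * abz
            rt = ra + t * (rb - ra)
            dx, dy, dz = cx - px, cy - py, cz - pz
            if dx * dx + dy * dy + dz * dz <= rt * rt:
                out[q] = True
                break
    return out


_M_E = 0.51099895  # MeV


@numba.njit(cache=True, inline="always")
def _interp_loglog(table, ln_e0, dln_e, n_e, energy):
    """Linear interpolation on the uniform-in-lnE grid of one table row."""
    x = (np.log(energy) - ln_e0) / dln_e
    if x <= 0.0:
        return table[0]
    if x >= n_e - 1:
        return table[n_e - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@numba.njit(cache=True, inline="always")
def _rotate(ux, uy, uz, theta, phi):
    """Rotate unit vector u by polar angle theta about itself, azimuth phi."""
    ct = np.cos(theta)
    st = np.sin(theta)
    cp = np.cos(phi)
    sp = np.sin(phi)
    # orthonormal frame (e1, e2, u)
    if abs(uz) < 0.99:
        e1x, e1y, e1z = uy, -ux, 0.0
    else:
        e1x, e1y, e1z = 0.0, uz, -uy
    norm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / norm, e1y / norm, e1z / norm
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    nx = ct * ux + st * (cp * e1x + sp * e2x)
    ny = ct * uy + st * (cp * e1y + sp * e2y)
    nz = ct * uz + st * (cp * e1z + sp * e2z)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@numba.njit(cache=True, inline="always")
def _highland_theta0(energy, step, inv_x0):
    """Gaussian multiple-scattering width (rad) for a step of length ``step`` cm."""
    t = step * inv_x0
    if t <= 0.0:
        return 0.0
    pc = np.sqrt(energy * (energy + 2.0 * _M_E))
    beta = pc / (energy + _M_E)
    corr = 1.0 + 0.038 * np.log(t)
    if corr < 0.25:
        corr = 0.25
    theta0 = 0.0136 / (beta * pc) * np.sqrt(t) * corr * 1000.0
    if theta0 > 1.4:
        theta0 = 1.4
    return theta0


@numba.njit(cache=True)
def transport_voxel(
    labels,
    origin,
    res,
    s_col,  # (2, nE) linear collision stopping power, MeV/cm
    s_rad,  # (2, nE) linear radiative stopping power, MeV/cm
    inv_x0,  # (2,) inverse radiation length, 1/cm
    ln_e0,
    dln_e,
    starts,  # (n, 3) cm
    dirs,  # (n, 3) unit vectors
    energies,  # (n,) MeV
    cutoff,  # MeV
    fmax,  # max fractional energy loss per step
    seed,
):
    """Condensed-history transport of n electrons through the label grid.

    Returns an (n, 5) array of per-history energy deposits
    [marrow, TBV, CBV, escaped, radiative] in MeV.  Void voxels and the
    outside of the grid are vacuum: a particle entering them escapes with its
    remaining kinetic energy.  Residual energy below the cutoff is deposited
    locally.
    """
    np.random.seed(seed)
    n = starts.shape[0]
    n_e = s_col.shape[1]
    out = np.zeros((n, 5), dtype=np.float64)
    nx, ny, nz = labels.shape
    eps = 1e-6 * res
    for q in range(n):
        x, y, z = starts[q, 0], starts[q, 1], starts[q, 2]
        ux, uy, uz = dirs[q, 0], dirs[q, 1], dirs[q, 2]
        e = energies[q]
        while True:
            i = int(np.floor((x - origin[0]) / res))
            j = int(np.floor((y - origin[1]) / res))
            k = int(np.floor((z - origin[2]) / res))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                out[q, 3] += e
                break
            lab = labels[i, j, k]
            if lab == LBL_VOID:
                out[q, 3] += e
                break
            dep_idx = 0 if lab == LBL_MARROW else (1 if lab == LBL_TRAB else 2)
            if e <= cutoff:
                out[q, dep_idx] += e
                break
            mat = 1 if lab == LBL_MARROW else 0
            sc = _interp_loglog(s_col[mat], ln_e0, dln_e, n_e, e)
            sr = _interp_loglog(s_rad[mat], ln_e0, dln_e, n_e, e)
            stot = sc + sr
            # distance to the next voxel face along u
            d_geom = 1e30
            if ux > 0.0:
                d_geom = ((i + 1) * res + origin[0] - x) / ux
            elif ux < 0.0:
                d_geom = (i * res + origin[0] - x) / ux
            if uy > 0.0:
                d = ((j + 1) * res + origin[1] - y) / uy
                if d < d_geom:
                    d_geom = d
            elif uy < 0.0:
                d = (j * res + origin[1] - y) / uy
                if d < d_geom:
                    d_geom = d
            if uz > 0.0:
                d = ((k + 1) * res + origin[2] - z) / uz
                if d < d_geom:
                    d_geom = d
            elif uz < 0.0:
                d = (k * res + origin[2] - z) / uz
                if d < d_geom:
                    d_geom = d
            if d_geom < 0.0:
                d_geom = 0.0
            d_loss = fmax * e / stot
            step = d_loss if d_loss < d_geom else d_geom
            # midpoint re-evaluation of the stopping power
            de = stot * step
            emid = e - 0.5 * de
            if emid < cutoff:
                emid = cutoff
            sc = _interp_loglog(s_col[mat], ln_e0, dln_e, n_e, emid)
            sr = _interp_loglog(s_rad[mat], ln_e0, dln_e, n_e, emid)
            stot = sc + sr
            de_col = sc * step
            de_rad = sr * step
            if e - de_col - de_rad <= cutoff:
                # terminal step: radiative share of the remaining energy
                # leaves as photons, the rest is deposited locally
                rad = e * sr / stot
                out[q, 4] += rad
                out[q, dep_idx] += e - rad
                break
            out[q, dep_idx] += de_col
            out[q, 4] += de_rad
            e -= de_col + de_rad
            x += ux * (step + eps)
            y += uy * (step + eps)
            z += uz * (step + eps)
            theta0 = _highland_theta0(emid, step, inv_x0[mat])
            if theta0 > 0.0:
                gx = np.random.normal(0.0, theta0)
                gy = np.random.normal(0.0, theta0)
                theta = np.sqrt(gx * gx + gy * gy)
                phi = np.random.uniform(0.0, 2.0 * np.pi)
                ux, uy, uz = _rotate(ux, uy, uz, theta, phi)
    return out


@numba.njit(cache=True)
def transport_homogeneous_radial(
    s_col_row,
    s_rad_row,
    inv_x0_s,
    ln_e0,
    dln_e,
    energies,
    cutoff,
    fmax,
    seed,
    bin_width,  # cm
    n_bins,
):
    """Point-source transport in an infinite homogeneous medium.

    Electrons start at the origin with isotropic directions; collision energy
    deposits are tallied into spherical shells of width ``bin_width`` around
    the origin (deposit binned at the step midpoint; the last bin collects
    overflow).  Returns (radial_edep [MeV], total_radiative [MeV]).
    """
    np.random.seed(seed)
    n = energies.shape[0]
    n_e = s_col_row.shape[0]
    edep = np.zeros(n_bins, dtype=np.float64)
    e_rad_tot = 0.0
    for q in range(n):
        cz = 2.0 * np.random.random() - 1.0
        sz = np.sqrt(max(0.0, 1.0 - cz * cz))
        phi = np.random.uniform(0.0, 2.0 * np.pi)
        ux, uy, uz = sz * np.cos(phi), sz * np.sin(phi), cz
        x = y = z = 0.0
        e = energies[q]
        while True:
            if e <= cutoff:
                r = np.sqrt(x * x + y * y + z * z)
                b = int(r / bin_width)
                if b >= n_bins:
                    b = n_bins - 1
                edep[b] += e
                break
            sc = _interp_loglog(s_col_row, ln_e0, dln_e, n_e, e)
            sr = _interp_loglog(s_rad_row, ln_e0, dln_e, n_e, e)
            stot = sc + sr
            step = fmax * e / stot
            de = stot * step
            emid = e - 0.5 * de
            if emid < cutoff:
                emid = cutoff
            sc = _interp_loglog(s_col_row, ln_e0, dln_e, n_e, emid)
            sr = _interp_loglog(s_rad_row, ln_e0, dln_e, n_e, emid)
            stot = sc + sr
            de_col = sc * step
            de_rad = sr * step
            mx = x + 0.5 * step * ux
            my = y + 0.5 * step * uy
            mz = z + 0.5 * step * uz
            r = np.sqrt(mx * mx + my * my + mz * mz)
            b = int(r / bin_width)
            if b >= n_bins:
                b = n_bins - 1
            if e - de_col - de_rad <= cutoff:
                rad = e * sr / stot
                e_rad_tot += rad
                edep[b] += e - rad
                break
            edep[b] += de_col
            e_rad_tot += de_rad
            e -= de_col + de_rad
            x += ux * step
            y += uy * step
            z += uz * step
            theta0 = _highland_theta0(emid, step, inv_x0_s)
            if theta0 > 0.0:
                gx = np.random.normal(0.0, theta0)
                gy = np.random.normal(0.0, theta0)
                theta = np.sqrt(gx * gx + gy * gy)
                phi = np.random.uniform(0.0, 2.0 * np.pi)
                ux, uy, uz = _rotate(ux, uy, uz, theta, phi)
    return edep, e_rad_tot
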