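"""Numba kernel: fixed-step ray marching with trilinear interpolation.

The attenuation grid passed in is padded by one voxel of zeros on every
side, so any sample whose unpadded continuous index lies in
[-0.5, n - 0.5] can be interpolated without bounds branches.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def integrate_rays(mu_padded, origin_pad, spacing, src, dirs, t0, t1, step):
    """Line integrals of ``mu_padded`` along rays ``src + t * dirs[i]``.

    Parameters
    ----------
    mu_padded : float32 (nx+2, ny+2, nz+2) attenuation, zero-padded.
    origin_pad : float64 (3,) world position of padded voxel (0,0,0) center.
    spacing : float64 (3,) voxel spacing, mm.
    src : float64 (3,) ray origin (volume frame).
    dirs : float64 (n, 3) unit ray directions.
    t0, t1 : float64 (n,) entry/exit ray parameters (mm); t1 <= t0 means miss.
    step : float, marching step in mm.

    Returns float64 (n,) integral values (units of mu * mm).
    """
    n = dirs.shape[0]
    out = np.zeros(n, dtype=np.float64)
    nx, ny, nz = mu_padded.shape
    ox, oy, oz = origin_pad[0], origin_pad[1], origin_pad[2]
    sx, sy, sz = spacing[0], spacing[1], spacing[2]
    px, py, pz = src[0], src[1], src[2]
    for i in range(n):
        a = t0[i]
        b = t1[i]
        if b <= a:
            continue
        dx = dirs[i, 0]
        dy = dirs[i, 1]
        dz = dirs[i, 2]
        nsteps = int((b - a) / step) + 1
        acc = 0.0
        for k in range(nsteps):
            t = a + (k + 0.5) * step
            if t >= b:
                break
            gx = (px + t * dx - ox) / sx
            gy = (py + t * dy - oy) / sy
            gz = (pz + t * dz - oz) / sz
            ix = int(np.floor(gx))
            iy = int(np.floor(gy))
            iz = int(np.floor(gz))
            if ix < 0 or iy < 0 or iz < 0 or ix > nx - 2 or iy > ny - 2 or iz > nz - 2:
                continue
            fx = gx - ix
            fy = gy - iy
            fz = gz - iz
            c000 = mu_padded[ix, iy, iz]
            c100 = mu_padded[ix + 1, iy, iz]
            c010 = mu_padded[ix, iy + 1, iz]
            c110 = mu_padded[ix + 1, iy + 1, iz]
            c001 = mu_padded[ix, iy, iz + 1]
            c101 = mu_padded[ix + 1, iy, iz + 1]
            c011 = mu_padded[ix, iy + 1, iz + 1]
            c111 = mu_padded[ix + 1, iy + 1, iz + 1]
            c00 = c000 * (1 - fx) + c100 * fx
            c10 = c010 * (1 - fx) + c110 * fx
            c01 = c001 * (1 - fx) + c101 * fx
            c11 = c011 * (1 - fx) + c111 * fx
            c0 = c00 * (1 - fy) + c10 * fy
            c1 = c01 * (1 - fy) + c11 * fy
            acc += c0 * (1 - fz) + c1 * fz
        out[i] = acc * step
    return out
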