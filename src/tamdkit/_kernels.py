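"""Numba kernels shared by the simulation and estimation modules.

Everything here operates on flat float64 coordinate vectors and plain
parameter arrays so that the hot loops (Langevin/TAMD integration, basis
accumulation, grid flooding) compile to machine code.  The object-level API
lives in the public modules; nothing in here is part of the public surface.
"""

import numpy as np
from numba import njit

from .units import ACC

# potential kind codes
KIND_HARMONIC = 0
KIND_DOUBLE_WELL = 1
KIND_MUELLER_BROWN = 2
KIND_TOY_FILTER = 3       # 3D ions + 1D gate appended
KIND_TOY_FILTER_AXIAL = 4  # 1D ions + 1D gate

# integrator status codes
STATUS_OK = 0
STATUS_ENERGY_OVERFLOW = 1
STATUS_CV_DIVERGENCE = 2

# Mueller-Brown constants (standard published values)
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


@njit(cache=True)
def pot_eg(kind, params, x, g):
    """Energy of one configuration; overwrites g with dE/dx."""
    n = x.shape[0]
    for i in range(n):
        g[i] = 0.0
    e = 0.0
    if kind == KIND_HARMONIC:
        k = params[0]
        for i in range(n):
            e += 0.5 * k * x[i] * x[i]
            g[i] = k * x[i]
    elif kind == KIND_DOUBLE_WELL:
        h, a, ky = params[0], params[1], params[2]
        u = (x[0] / a) * (x[0] / a) - 1.0
        e = h * u * u + 0.5 * ky * x[1] * x[1]
        g[0] = 4.0 * h * u * x[0] / (a * a)
        g[1] = ky * x[1]
    elif kind == KIND_MUELLER_BROWN:
        for k in range(4):
            dx = x[0] - _MB_x0[k]
            dy = x[1] - _MB_y0[k]
            ex = _MB_A[k] * np.exp(_MB_a[k] * dx * dx + _MB_b[k] * dx * dy
                                   + _MB_c[k] * dy * dy)
            e += ex
            g[0] += ex * (2.0 * _MB_a[k] * dx + _MB_b[k] * dy)
            g[1] += ex * (2.0 * _MB_c[k] * dy + _MB_b[k] * dx)
    elif kind == KIND_TOY_FILTER or kind == KIND_TOY_FILTER_AXIAL:
        n_ions = int(params[0])
        n_wells = int(params[1])
        radius = params[2]
        k_radial = params[3]
        coupling = params[4]
        gate_h = params[5]
        gate_a = params[6]
        z_mid = params[7]
        z_scale = params[8]
        sigma = params[9]
        rep_a = params[10]
        rep_w = params[11]
        z_lo = params[12]
        z_hi = params[13]
        k_dom = params[14]
        centers = params[15:15 + n_wells]
        depths = params[15 + n_wells:15 + 2 * n_wells]

        stride = 3 if kind == KIND_TOY_FILTER else 1
        zoff = 2 if kind == KIND_TOY_FILTER else 0
        gi = n_ions * stride  # gate coordinate index
        gate = x[gi]

        zbar = 0.0
        for i in range(n_ions):
            zi = x[i * stride + zoff]
            zbar += zi / n_ions
            # Gaussian wells along z
            for w in range(n_wells):
                dz = zi - centers[w]
                ew = -depths[w] * np.exp(-dz * dz / (2.0 * sigma * sigma))
                e += ew
                g[i * stride + zoff] += -ew * dz / (sigma * sigma)
            # soft half-harmonic z-domain confinement
            if zi > z_hi:
                e += 0.5 * k_dom * (zi - z_hi) ** 2
                g[i * stride + zoff] += k_dom * (zi - z_hi)
            elif zi < z_lo:
                e += 0.5 * k_dom * (zi - z_lo) ** 2
                g[i * stride + zoff] += k_dom * (zi - z_lo)
            # radial cylinder confinement (3D variant only)
            if kind == KIND_TOY_FILTER:
                xi = x[i * stride]
                yi = x[i * stride + 1]
                r = np.sqrt(xi * xi + yi * yi)
                if r > radius:
                    dr = r - radius
                    e += 0.5 * k_radial * dr * dr
                    if r > 1e-12:
                        g[i * stride] += k_radial * dr * xi / r
                        g[i * stride + 1] += k_radial * dr * yi / r
        # axial pairwise repulsion between ions
        for i in range(n_ions):
            for j in range(i + 1, n_ions):
                dz = x[i * stride + zoff] - x[j * stride + zoff]
                er = rep_a * np.exp(-dz * dz / (2.0 * rep_w * rep_w))
                e += er
                fij = -er * dz / (rep_w * rep_w)
                g[i * stride + zoff] += fij
                g[j * stride + zoff] -= fij
        # gate double well
        u = (gate / gate_a) * (gate / gate_a) - 1.0
        e += gate_h * u * u
        g[gi] += 4.0 * gate_h * u * gate / (gate_a * gate_a)
        # gate-ion coupling, saturated so it stays bounded away from the
        # well region instead of dominating the landscape at the domain edges
        s = np.tanh((zbar - z_mid) / z_scale)
        e += coupling * (gate / gate_a) * s
        g[gi] += coupling * s / gate_a
        dsdz = (1.0 - s * s) / z_scale
        for i in range(n_ions):
            g[i * stride + zoff] += coupling * (gate / gate_a) * dsdz / n_ions
    return e


@njit(cache=True)
def pot_energy_batch(kind, params, X):
    out = np.empty(X.shape[0])
    g = np.empty(X.shape[1])
    for i in range(X.shape[0]):
        out[i] = pot_eg(kind, params, X[i], g)
    return out


@njit(cache=True)
def _plateau(u, lo, hi, w):
    """C1 smooth plateau: 0 outside [lo,hi], 1 on [lo+w, hi-w]. Returns (S, dS/du)."""
    if u <= lo or u >= hi:
        return 0.0, 0.0
    if u < lo + w:
        t = (u - lo) / w
        return 3.0 * t * t - 2.0 * t * t * t, (6.0 * t - 6.0 * t * t) / w
    if u > hi - w:
        t = (hi - u) / w
        return 3.0 * t * t - 2.0 * t * t * t, -(6.0 * t - 6.0 * t * t) / w
    return 1.0, 0.0


@njit(cache=True)
def restraints_eg(walls, posres, excl, x, g):
    """Adds restraint gradients into g, returns restraint energy.

    walls rows:  [coord_index, bound, side(+1: penalize c>bound), kappa]
    posres rows: [coord_index, reference, kappa]
    excl rows:   [base_index, xmin, xmax, ymin, ymax, zmin, zmax, k, ramp]
    """
    e = 0.0
    for r in range(walls.shape[0]):
        i = int(walls[r, 0])
        bound = walls[r, 1]
        side = walls[r, 2]
        kap = walls[r, 3]
        d = (x[i] - bound) * side
        if d > 0.0:
            e += 0.5 * kap * d * d
            g[i] += kap * d * side
    for r in range(posres.shape[0]):
        i = int(posres[r, 0])
        d = x[i] - posres[r, 1]
        kap = posres[r, 2]
        e += 0.5 * kap * d * d
        g[i] += kap * d
    for r in range(excl.shape[0]):
        b = int(excl[r, 0])
        k = excl[r, 7]
        w = excl[r, 8]
        sx, dsx = _plateau(x[b], excl[r, 1], excl[r, 2], w)
        sy, dsy = _plateau(x[b + 1], excl[r, 3], excl[r, 4], w)
        sz, dsz = _plateau(x[b + 2], excl[r, 5], excl[r, 6], w)
        e += k * sx * sy * sz
        g[b] += k * dsx * sy * sz
        g[b + 1] += k * sx * dsy * sz
        g[b + 2] += k * sx * sy * dsz
    return e


@njit(cache=True)
def _fill_gaussians(buf):
    """Box-Muller gaussians from the uniform stream.

    Drawn explicitly (not via standard_normal) so that reseeding fully
    determines the stream: numba's cached second Box-Muller deviate is not
    cleared by np.random.seed.
    """
    i = 0
    nb = buf.shape[0]
    while i < nb:
        u1 = np.random.random()
        u2 = np.random.random()
        r = np.sqrt(-2.0 * np.log(u1 + 1e-300))
        buf[i] = r * np.cos(2.0 * np.pi * u2)
        if i + 1 < nb:
            buf[i + 1] = r * np.sin(2.0 * np.pi * u2)
        i += 2


@njit(cache=True)
def run_dynamics(kind, params, x0, v0, mass, kT, gamma, dt, n_steps, save_every,
                 walls, posres, excl,
                 tamd_on, W, z0, kappa, gamma_bar, kT_bar, z_div_limit, seed):
    """BAOAB Langevin on x; optional overdamped Euler-Maruyama auxiliaries z.

    mass is per-coordinate (amu).  Returns (times, xs, zs, thetas, status,
    n_saved).  Auxiliary spring force on x is -kappa*(theta_j - z_j)*W_j;
    z_j feels +kappa*(theta_j - z_j) plus noise at kT_bar.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    M = W.shape[0]
    x = x0.copy()
    v = v0.copy()
    z = z0.copy()
    theta = np.zeros(M)
    g = np.empty(n)
    gr = np.zeros(n)
    noise = np.empty(n + M)

    n_saved = n_steps // save_every
    times = np.empty(n_saved)
    xs = np.empty((n_saved, n))
    zs = np.empty((n_saved, M))
    thetas = np.empty((n_saved, M))

    c1 = np.exp(-gamma * dt)
    noise_fac = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig = np.empty(n)
    for i in range(n):
        sig[i] = np.sqrt(kT * ACC / mass[i]) * noise_fac
    z_step = dt / gamma_bar
    z_noise = np.sqrt(2.0 * kT_bar * dt / gamma_bar)

    # initial force
    e = pot_eg(kind, params, x, g)
    e += restraints_eg(walls, posres, excl, x, gr)
    for i in range(n):
        g[i] += gr[i]
        gr[i] = 0.0
    if tamd_on:
        for j in range(M):
            th = 0.0
            for i in range(n):
                th += W[j, i] * x[i]
            theta[j] = th
            d = th - z[j]
            e += 0.5 * kappa * d * d
            for i in range(n):
                if W[j, i] != 0.0:
                    g[i] += kappa * d * W[j, i]

    status = STATUS_OK
    frame = 0
    for step in range(n_steps):
        # B (half kick)
        for i in range(n):
            v[i] -= 0.5 * dt * g[i] * ACC / mass[i]
        # A (half drift)
        for i in range(n):
            x[i] += 0.5 * dt * v[i]
        # O (full OU)
        _fill_gaussians(noise)
        for i in range(n):
            v[i] = c1 * v[i] + sig[i] * noise[i]
        # A (half drift)
        for i in range(n):
            x[i] += 0.5 * dt * v[i]
        # auxiliary update (overdamped, first order)
        if tamd_on:
            for j in range(M):
                th = 0.0
                for i in range(n):
                    th += W[j, i] * x[i]
                theta[j] = th
                z[j] += z_step * kappa * (th - z[j]) \
                    + z_noise * noise[n + j]
        # recompute force
        e = pot_eg(kind, params, x, g)
        e += restraints_eg(walls, posres, excl, x, gr)
        for i in range(n):
            g[i] += gr[i]
            gr[i] = 0.0
        if tamd_on:
            for j in range(M):
                th = 0.0
                for i in range(n):
                    th += W[j, i] * x[i]
                theta[j] = th
                d = th - z[j]
                e += 0.5 * kappa * d * d
                for i in range(n):
                    if W[j, i] != 0.0:
                        g[i] += kappa * d * W[j, i]
        # B (half kick)
        for i in range(n):
            v[i] -= 0.5 * dt * g[i] * ACC / mass[i]

        if (step + 1) % save_every == 0:
            times[frame] = (step + 1) * dt
            for i in range(n):
                xs[frame, i] = x[i]
            for j in range(M):
                zs[frame, j] = z[j]
                thetas[frame, j] = theta[j]
            frame += 1
            if e > 1e8 or not np.isfinite(e):
                status = STATUS_ENERGY_OVERFLOW
                break
            if tamd_on:
                for j in range(M):
                    if abs(theta[j] - z[j]) > z_div_limit:
                        status = STATUS_CV_DIVERGENCE
                        break
                if status != STATUS_OK:
                    break
    return times[:frame], xs[:frame], zs[:frame], thetas[:frame], status, frame


@njit(cache=True)
def accumulate_1d(A, b, count, x0n, h, n_nodes, zs, fs):
    """Running-sum assembly of the 1D gradient-matching normal equations."""
    n_out = 0
    inv = 1.0 / h
    for t in range(zs.shape[0]):
        z = zs[t]
        if z < x0n or z > x0n + (n_nodes - 1) * h:
            n_out += 1
            continue
        i = int((z - x0n) * inv)
        if i > n_nodes - 2:
            i = n_nodes - 2
        # grad(phi_i) = -1/h, grad(phi_{i+1}) = +1/h within the cell
        A[i, i] += inv * inv
        A[i + 1, i + 1] += inv * inv
        A[i, i + 1] -= inv * inv
        A[i + 1, i] -= inv * inv
        f = fs[t]
        b[i] += inv * f
        b[i + 1] -= inv * f
        count[i] += 1
        count[i + 1] += 1
    return n_out


@njit(cache=True)
def accumulate_2d(A, b, count, x0n, y0n, hx, hy, nx, ny, zx, zy, fx, fy):
    """2D assembly on a regular grid split into lower-left triangles.

    Node id = ix*ny + iy.  In each cell the three active chapeau gradients
    are element-wise constant, so the assembly is exact.
    """
    n_out = 0
    gm = np.empty((3, 2))
    vid = np.empty(3, dtype=np.int64)
    for t in range(zx.shape[0]):
        px = zx[t]
        py = zy[t]
        if px < x0n or px > x0n + (nx - 1) * hx or py < y0n or py > y0n + (ny - 1) * hy:
            n_out += 1
            continue
        i = int((px - x0n) / hx)
        if i > nx - 2:
            i = nx - 2
        j = int((py - y0n) / hy)
        if j > ny - 2:
            j = ny - 2
        s = (px - (x0n + i * hx)) / hx
        u = (py - (y0n + j * hy)) / hy
        if s + u <= 1.0:
            vid[0] = i * ny + j          # phi = 1-s-u
            vid[1] = (i + 1) * ny + j    # phi = s
            vid[2] = i * ny + (j + 1)    # phi = u
            gm[0, 0] = -1.0 / hx
            gm[0, 1] = -1.0 / hy
            gm[1, 0] = 1.0 / hx
            gm[1, 1] = 0.0
            gm[2, 0] = 0.0
            gm[2, 1] = 1.0 / hy
        else:
            vid[0] = (i + 1) * ny + (j + 1)  # phi = s+u-1
            vid[1] = (i + 1) * ny + j        # phi = 1-u
            vid[2] = i * ny + (j + 1)        # phi = 1-s
            gm[0, 0] = 1.0 / hx
            gm[0, 1] = 1.0 / hy
            gm[1, 0] = 0.0
            gm[1, 1] = -1.0 / hy
            gm[2, 0] = -1.0 / hx
            gm[2, 1] = 0.0
        for m in range(3):
            b[vid[m]] -= gm[m, 0] * fx[t] + gm[m, 1] * fy[t]
            count[vid[m]] += 1
            for nn in range(3):
                A[vid[m], vid[nn]] += gm[m, 0] * gm[nn, 0] + gm[m, 1] * gm[nn, 1]
    return n_out


@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def minimax_saddle(E, nx, ny, order, ia, ib):
    """Bottleneck (minimax) saddle between grid cells ia and ib.

    Floods cells in ascending energy, merging 4-neighbour components; the
    cell whose activation first connects ia and ib is the minimax saddle.
    Returns (flat_index, energy).
    """
    n = nx * ny
    parent = np.empty(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        parent[i] = i
    for t in range(n):
        c = order[t]
        active[c] = 1
        ix = c // ny
        iy = c % ny
        if ix > 0 and active[c - ny]:
            ra, rb = _uf_find(parent, c), _uf_find(parent, c - ny)
            if ra != rb:
                parent[ra] = rb
        if ix < nx - 1 and active[c + ny]:
            ra, rb = _uf_find(parent, c), _uf_find(parent, c + ny)
            if ra != rb:
                parent[ra] = rb
        if iy > 0 and active[c - 1]:
            ra, rb = _uf_find(parent, c), _uf_find(parent, c - 1)
            if ra != rb:
                parent[ra] = rb
        if iy < ny - 1 and active[c + 1]:
            ra, rb = _uf_find(parent, c), _uf_find(parent, c + 1)
            if ra != rb:
                parent[ra] = rb
        if active[ia] and active[ib]:
            if _uf_find(parent, ia) == _uf_find(parent, ib):
                return c, E[c]
    return -1, np.nan
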