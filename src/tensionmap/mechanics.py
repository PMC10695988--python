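"""Traction-force microscopy and internal force balance.

Pipeline: bead-image drift registration → PIV displacement field →
Fourier-transform traction cytometry (FTTC) → plane-stress internal force
balance.

FTTC inverts the elastic half-space (Boussinesq) relation between surface
tractions T and surface displacements u.  In Fourier space, for wavevector
k on a gel of Young's modulus E and Poisson ratio ν::

    ũ(k) = G̃(k) · T̃(k),
    G̃(k) = 2(1+ν)/(E·k³) · [[(1−ν)k² + ν·ky²,  −ν·kx·ky       ],
                             [−ν·kx·ky,          (1−ν)k² + ν·kx²]]

The forward map doubles as the independent oracle for the inversion, which
uses zeroth-order Tikhonov regularization and zeroes the DC mode (no net
translation, hence zero net reconstructed force).

The internal force balance solves 2D plane-stress equilibrium over the cell
domain — ∇·σ + t = 0 with t = −T (the substrate's reaction to the cell's
traction), traction-free cell boundary, homogeneous isotropic elasticity
with ν_cell = 0.5 and unit thickness — by bilinear finite elements on the
traction grid.  |F̃| is the magnitude of the mean of the in-plane principal
stresses times thickness; it is independent of the (arbitrary) cell Young's
modulus because stresses scale as E·K⁻¹·f.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage.registration import phase_cross_correlation

from .types import DisplacementField, InternalForceMap, TractionField

__all__ = [
    "register_drift",
    "piv_displacements",
    "forward_boussinesq",
    "fttc_tractions",
    "select_lambda_lcurve",
    "internal_force_balance",
]


# ---------------------------------------------------------------------------
# Registration + PIV
# ---------------------------------------------------------------------------

def register_drift(image, reference, upsample=100, min_quality=0.05):
    """Subpixel rigid drift between a frame and its reference.

    Returns ``((dy, dx), corrected)`` where ``corrected`` is the image
    shifted back onto the reference.  Raises if the correlation peak is too
    weak to trust.
    """
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    shift, error, _ = phase_cross_correlation(reference, image,
                                              upsample_factor=upsample,
                                              normalization=None)
    a = reference - reference.mean()
    b = image - image.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    quality = float(np.abs(np.vdot(a, b)) / denom) if denom > 0 else 1.0
    if not np.array_equal(image, reference) and quality < min_quality:
        raise ValueError(f"correlation peak too weak (quality {quality:.3f})")
    corrected = ndimage.shift(image, shift, order=3, mode="nearest")
    # report the drift of the image relative to the reference
    return (-float(shift[0]), -float(shift[1])), corrected


def _gauss_subpixel(c, py, px):
    """Three-point Gaussian peak interpolation in each axis."""
    def offset(m1, m0, p1):
        m1, m0, p1 = max(m1, 1e-12), max(m0, 1e-12), max(p1, 1e-12)
        denom = 2 * np.log(m1) - 4 * np.log(m0) + 2 * np.log(p1)
        if denom >= 0:
            return 0.0
        return (np.log(m1) - np.log(p1)) / denom

    dy = offset(c[py - 1, px], c[py, px], c[py + 1, px]) if 0 < py < c.shape[0] - 1 else 0.0
    dx = offset(c[py, px - 1], c[py, px], c[py, px + 1]) if 0 < px < c.shape[1] - 1 else 0.0
    return dy, dx


def piv_displacements(reference, deformed, grid_spacing, window=32,
                      pixel_size=1.0, outlier_threshold=2.0) -> DisplacementField:
    """PIV displacement field by windowed normalized cross-correlation.

    ``grid_spacing`` is in µm (converted to pixels via ``pixel_size``);
    interrogation windows of ``window`` px are correlated by FFT with a
    three-point Gaussian subpixel peak fit.  Vectors failing the normalized
    -median universal outlier test are replaced by the local median and
    flagged.  Windows without signal get quality 0 and are treated as
    outliers.

    Returns displacements in µm on the µm grid.
    """
    ref = np.asarray(reference, float)
    de = np.asarray(deformed, float)
    if ref.shape != de.shape:
        raise ValueError("image shapes differ")
    step = max(int(round(grid_spacing / pixel_size)), 1)
    half = window // 2
    rows = np.arange(half, ref.shape[0] - half + 1, step)
    cols = np.arange(half, ref.shape[1] - half + 1, step)
    ny, nx = rows.size, cols.size
    # linear (zero-padded) correlation with overlap normalization removes
    # the window-truncation bias of circular correlation toward zero lag
    lags = np.arange(2 * window) - window
    overlap = np.maximum(window - np.abs(lags), 1).astype(float)
    W = np.outer(overlap, overlap)
    s_max = window // 3          # search radius in lag space
    centre = window
    search = (slice(centre - s_max, centre + s_max + 1),) * 2

    def one_pass(offset):
        u = np.zeros((ny, nx, 2))
        quality = np.zeros((ny, nx))
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                oy = int(round(offset[i, j, 1]))
                ox = int(round(offset[i, j, 0]))
                r2, c2 = r + oy, c + ox
                if not (half <= r2 <= de.shape[0] - half
                        and half <= c2 <= de.shape[1] - half):
                    oy = ox = 0
                    r2, c2 = r, c
                a = ref[r - half:r + half, c - half:c + half]
                b = de[r2 - half:r2 + half, c2 - half:c2 + half]
                a = a - a.mean()
                b = b - b.mean()
                na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
                if na < 1e-9 or nb < 1e-9:
                    continue
                ap = np.zeros((2 * window, 2 * window))
                bp = np.zeros((2 * window, 2 * window))
                ap[:window, :window] = a
                bp[:window, :window] = b
                corr = np.real(np.fft.ifft2(np.conj(np.fft.fft2(ap)) * np.fft.fft2(bp)))
                corr = np.fft.fftshift(corr) / W
                sub = corr[search]
                py, px = np.unravel_index(np.argmax(sub), sub.shape)
                py += centre - s_max
                px += centre - s_max
                dy, dx = _gauss_subpixel(corr, py, px)
                u[i, j, 1] = oy + (py - centre) + dy          # uy in px
                u[i, j, 0] = ox + (px - centre) + dx          # ux in px
                ov = overlap[py] * overlap[px]
                quality[i, j] = float(corr[py, px] * ov / (na * nb))
        return u, quality

    # two passes: the second re-interrogates with integer window offsets so
    # the correlation peak sits near zero lag (best subpixel regime)
    u, quality = one_pass(np.zeros((ny, nx, 2)))
    u, quality = one_pass(np.round(u))
    # universal outlier detection (normalized median test)
    replaced = np.zeros((ny, nx), bool)
    eps = 0.1
    med = np.stack([ndimage.median_filter(u[..., k], size=3, mode="nearest")
                    for k in range(2)], axis=-1)
    resid = np.hypot(*(u - med).transpose(2, 0, 1))
    fluct = np.stack([ndimage.median_filter(np.abs(u[..., k] - med[..., k]),
                                            size=3, mode="nearest")
                      for k in range(2)], axis=-1)
    norm_res = resid / (np.hypot(fluct[..., 0], fluct[..., 1]) + eps)
    bad = (norm_res > outlier_threshold) | (quality <= 0)
    u[bad] = med[bad]
    replaced[bad] = True
    return DisplacementField(
        x=cols * pixel_size, y=rows * pixel_size, u=u * pixel_size,
        quality=np.clip(quality, 0, 1), replaced=replaced,
        grid_spacing=step * pixel_size)


# ---------------------------------------------------------------------------
# Boussinesq forward / inverse (FTTC)
# ---------------------------------------------------------------------------

def _boussinesq_kernel(ny, nx, h, E, nu):
    """Green's tensor G̃(k) on the FFT grid; zero at k = 0."""
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=h)
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=h)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    k2 = KX ** 2 + KY ** 2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2 * (1 + nu) / (E * k2 * k)
        Gxx = pref * ((1 - nu) * k2 + nu * KY ** 2)
        Gyy = pref * ((1 - nu) * k2 + nu * KX ** 2)
        Gxy = pref * (-nu * KX * KY)
    for arr in (Gxx, Gyy, Gxy):
        arr[0, 0] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    return Gxx, Gyy, Gxy


def forward_boussinesq(traction: TractionField, E_gel=None, nu=None) -> DisplacementField:
    """Surface displacement of an elastic half-space under a traction field.

    Spectral convolution of T with the Boussinesq Green's tensor on the
    traction grid; the k = 0 (rigid translation) mode is set to zero.
    ν = 0.5 is the incompressible limit and is handled by the same kernel.
    """
    E = E_gel if E_gel is not None else traction.E_gel
    nu = nu if nu is not None else traction.nu
    T = np.asarray(traction.T, float)
    ny, nx = T.shape[:2]
    h = traction.grid_spacing
    Gxx, Gyy, Gxy = _boussinesq_kernel(ny, nx, h, E, nu)
    Tx = np.fft.fft2(T[..., 0])
    Ty = np.fft.fft2(T[..., 1])
    ux = np.real(np.fft.ifft2(Gxx * Tx + Gxy * Ty))
    uy = np.real(np.fft.ifft2(Gxy * Tx + Gyy * Ty))
    u = np.stack([ux, uy], axis=-1)
    return DisplacementField(x=traction.x, y=traction.y, u=u,
                             quality=np.ones((ny, nx)),
                             replaced=np.zeros((ny, nx), bool),
                             grid_spacing=h)


def fttc_tractions(disp: DisplacementField, E_gel=2800.0, nu=0.5,
                   lam=0.0) -> TractionField:
    """Regularized Fourier-transform traction cytometry.

    Per-wavevector Tikhonov solve ``T̃ = (G̃ᵀG̃ + λ²I)⁻¹ G̃ᵀ ũ``; the DC
    mode is zeroed, so the reconstructed field carries no net force by
    construction (the residual is still measured and reported).
    """
    if lam < 0:
        raise ValueError("regularization parameter must be nonnegative")
    u = np.asarray(disp.u, float)
    ny, nx = u.shape[:2]
    if ny < 8 or nx < 8:
        raise ValueError("grid too small for FTTC (need at least 8x8)")
    h = disp.grid_spacing
    Gxx, Gyy, Gxy = _boussinesq_kernel(ny, nx, h, E_gel, nu)
    Ux = np.fft.fft2(u[..., 0])
    Uy = np.fft.fft2(u[..., 1])
    # per-k 2x2 symmetric solve, vectorised
    A11 = Gxx * Gxx + Gxy * Gxy + lam ** 2
    A22 = Gxy * Gxy + Gyy * Gyy + lam ** 2
    A12 = Gxx * Gxy + Gxy * Gyy
    b1 = Gxx * Ux + Gxy * Uy
    b2 = Gxy * Ux + Gyy * Uy
    det = A11 * A22 - A12 * A12
    with np.errstate(divide="ignore", invalid="ignore"):
        Tx = (A22 * b1 - A12 * b2) / det
        Ty = (A11 * b2 - A12 * b1) / det
    for arr in (Tx, Ty):
        arr[0, 0] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    tx = np.real(np.fft.ifft2(Tx))
    ty = np.real(np.fft.ifft2(Ty))
    T = np.stack([tx, ty], axis=-1)
    dA = (h * 1e-6) ** 2
    net = (float(T[..., 0].sum() * dA), float(T[..., 1].sum() * dA))
    return TractionField(x=disp.x, y=disp.y, T=T, grid_spacing=h,
                         E_gel=E_gel, nu=nu, lam=lam, net_force=net)


def select_lambda_lcurve(disp: DisplacementField, E_gel=2800.0, nu=0.5,
                         lambdas=None):
    """L-curve helper: pick λ at the corner of log‖residual‖ vs log‖T‖.

    Scans candidate λ values, computes the forward-model residual and the
    solution norm for each, and returns the λ maximizing the discrete
    curvature of the L-curve.
    """
    if lambdas is None:
        Gxx, Gyy, _ = _boussinesq_kernel(*disp.u.shape[:2],
                                         disp.grid_spacing, E_gel, nu)
        g0 = np.median(np.abs(Gxx[np.abs(Gxx) > 0]))
        lambdas = g0 * np.logspace(-3, 2, 24)
    rho, eta = [], []
    for lam in lambdas:
        tf = fttc_tractions(disp, E_gel, nu, lam)
        back = forward_boussinesq(tf, E_gel, nu)
        rho.append(np.linalg.norm(back.u - disp.u))
        eta.append(np.linalg.norm(tf.T))
    lr, le = np.log(np.asarray(rho) + 1e-300), np.log(np.asarray(eta) + 1e-300)
    # discrete curvature of the parametric curve (lr, le)
    d1r, d1e = np.gradient(lr), np.gradient(le)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    curv = (d1r * d2e - d1e * d2r) / np.power(d1r ** 2 + d1e ** 2, 1.5)
    return float(np.asarray(lambdas)[np.nanargmax(curv)])


# ---------------------------------------------------------------------------
# Plane-stress force balance
# ---------------------------------------------------------------------------

def _element_stiffness(h, nu):
    """4-node bilinear quad plane-stress stiffness (E = 1), 2x2 Gauss."""
    D = (1.0 / (1 - nu ** 2)) * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, (1 - nu) / 2.0],
    ])
    gp = [-1 / np.sqrt(3), 1 / np.sqrt(3)]
    K = np.zeros((8, 8))
    for xi in gp:
        for et in gp:
            dN = np.array([
                [-(1 - et), (1 - et), (1 + et), -(1 + et)],
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
            ]) / 4.0
            J = h / 2.0
            dNdx = dN / J
            B = np.zeros((3, 8))
            for a in range(4):
                B[0, 2 * a] = dNdx[0, a]
                B[1, 2 * a + 1] = dNdx[1, a]
                B[2, 2 * a] = dNdx[1, a]
                B[2, 2 * a + 1] = dNdx[0, a]
            K += B.T @ D @ B * (J * J)
    return K, D


def internal_force_balance(traction: TractionField, cell_mask,
                           nu_cell=0.5, thickness=1.0,
                           balance_tol=0.2) -> InternalForceMap:
    """Internal force magnitude |F̃| by plane-stress force balance.

    Solves ∇·σ + t = 0 over the cell domain (t = −T, the substrate
    reaction), traction-free boundary, homogeneous isotropic elasticity, by
    bilinear FEM on the traction grid; rigid-body motion is removed by
    Lagrange constraints.  |F̃| = |(σ₁ + σ₂)/2| × thickness per node, zero
    outside the cell.

    ``balance_tol`` bounds the allowed net-force imbalance of the input,
    relative to the total traction magnitude; the (small) residual is
    subtracted uniformly over the cell before solving and the mask is warned
    about if it is not simply connected.
    """
    T = np.asarray(traction.T, float)
    mask = np.asarray(cell_mask, bool)
    ny, nx = mask.shape
    if T.shape[:2] != (ny, nx):
        raise ValueError("traction grid and mask shapes differ")
    h = traction.grid_spacing
    n_cell = int(mask.sum())
    if n_cell < 4:
        raise ValueError("cell mask too small")
    # connectivity / topology warnings
    n_comp = ndimage.label(mask)[1]
    filled = ndimage.binary_fill_holes(mask)
    if n_comp != 1 or not np.array_equal(filled, mask):
        warnings.warn("cell mask is not simply connected")
    # check and remove net-force residual
    tot = np.abs(T[mask]).sum()
    net = T[mask].sum(axis=0)
    if tot > 0 and np.linalg.norm(net) / tot > balance_tol:
        raise ValueError(
            f"input tractions unbalanced: |net|/Σ|T| = {np.linalg.norm(net) / tot:.3f}")
    load = -T.copy()
    load[mask] += net[None, :] / n_cell      # uniform correction of residual
    load[~mask] = 0.0

    # nodes inside the mask; elements whose 4 corners are inside
    node_id = -np.ones((ny, nx), int)
    idx = np.argwhere(mask)
    for n, (i, j) in enumerate(idx):
        node_id[i, j] = n
    n_nodes = len(idx)
    elems = []
    for i in range(ny - 1):
        for j in range(nx - 1):
            if mask[i, j] and mask[i, j + 1] and mask[i + 1, j + 1] and mask[i + 1, j]:
                elems.append((node_id[i, j], node_id[i, j + 1],
                              node_id[i + 1, j + 1], node_id[i + 1, j],
                              i, j))
    if not elems:
        raise ValueError("no complete elements inside the mask")
    Ke, D = _element_stiffness(h, nu_cell)
    rows_, cols_, vals_ = [], [], []
    f = np.zeros(2 * n_nodes)
    # element node order: (i,j), (i,j+1), (i+1,j+1), (i+1,j) -> local x=cols, y=rows
    for (n0, n1, n2, n3, i, j) in elems:
        nodes = (n0, n1, n2, n3)
        dofs = np.array([[2 * n, 2 * n + 1] for n in nodes]).ravel()
        for a in range(8):
            rows_.extend([dofs[a]] * 8)
            cols_.extend(dofs)
            vals_.extend(Ke[a])
        # consistent lumped load: each corner gets h²/4 of its nodal load
        coords = [(i, j), (i, j + 1), (i + 1, j + 1), (i + 1, j)]
        for a, (ci, cj) in enumerate(coords):
            f[dofs[2 * a]] += load[ci, cj, 0] * h * h / 4.0
            f[dofs[2 * a + 1]] += load[ci, cj, 1] * h * h / 4.0
    K = sparse.csr_matrix((vals_, (rows_, cols_)), shape=(2 * n_nodes, 2 * n_nodes))
    # rigid-body constraints: zero mean translation, zero mean rotation
    ys = idx[:, 0] * h
    xs = idx[:, 1] * h
    C = np.zeros((3, 2 * n_nodes))
    C[0, 0::2] = 1.0
    C[1, 1::2] = 1.0
    C[2, 0::2] = -(ys - ys.mean())
    C[2, 1::2] = (xs - xs.mean())
    A = sparse.bmat([[K, sparse.csr_matrix(C.T)],
                     [sparse.csr_matrix(C), None]], format="csc")
    rhs = np.concatenate([f, np.zeros(3)])
    sol = spsolve(A, rhs)
    u = sol[: 2 * n_nodes].reshape(-1, 2)

    # stresses at element centres, scattered back to nodes
    sxx = np.zeros(n_nodes)
    syy = np.zeros(n_nodes)
    sxy = np.zeros(n_nodes)
    cnt = np.zeros(n_nodes)
    dN0 = np.array([[-1, 1, 1, -1], [-1, -1, 1, 1]]) / 4.0   # at centre
    J = h / 2.0
    Bc = np.zeros((3, 8))
    for a in range(4):
        Bc[0, 2 * a] = dN0[0, a] / J
        Bc[1, 2 * a + 1] = dN0[1, a] / J
        Bc[2, 2 * a] = dN0[1, a] / J
        Bc[2, 2 * a + 1] = dN0[0, a] / J
    for (n0, n1, n2, n3, i, j) in elems:
        nodes = (n0, n1, n2, n3)
        ue = np.array([[u[n, 0], u[n, 1]] for n in nodes]).ravel()
        sig = D @ (Bc @ ue)
        for n in nodes:
            sxx[n] += sig[0]
            syy[n] += sig[1]
            sxy[n] += sig[2]
            cnt[n] += 1.0
    cnt[cnt == 0] = 1.0
    sxx /= cnt
    syy /= cnt
    sxy /= cnt
    Sxx = np.zeros((ny, nx))
    Syy = np.zeros((ny, nx))
    Sxy = np.zeros((ny, nx))
    Sxx[mask] = sxx
    Syy[mask] = syy
    Sxy[mask] = sxy
    F = np.where(mask, np.abs((Sxx + Syy) / 2.0) * thickness, 0.0)
    return InternalForceMap(F=F, sigma_xx=Sxx, sigma_yy=Syy, sigma_xy=Sxy,
                            grid_spacing=h, thickness=thickness)
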