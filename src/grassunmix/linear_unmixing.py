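"""Per-pixel linear spectral unmixing under configurable constraints.

The linear mixing model treats each pixel's reflectance r (over the valid
bands) as a weighted sum of K endmember spectra E_1..E_K, the weights a_i
being the sub-pixel fractional abundances:

    r = sum_i a_i * E_i + noise

Four constraint regimes are solved, all minimising ||E a - r||^2 over the
valid bands:

* ``ols``  — unconstrained least squares;
* ``sto``  — sum-to-one (sum a_i = 1), solved in closed form via KKT;
* ``nnls`` — non-negative (a_i >= 0), Lawson-Hanson;
* ``fcls`` — fully constrained (both), solved by an exact active-set
  quadratic program on the unit simplex.

The fully constrained mode is the production setting: its solutions are
proper fractions that sum to one per pixel.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.optimize

from .errors import CollinearEndmembersError, DataError, NumericalError
from .types import EndmemberLibrary, FractionStack, SpectralCube

__all__ = ["MODES", "unmix_pixel", "unmix_cube", "brute_force_unmix"]

MODES = ("ols", "sto", "nnls", "fcls")

#: Relative singular-value cutoff declaring the endmember matrix
#: rank-deficient.
RANK_TOL = 1e-10

#: Tolerance on constraint satisfaction (simplex feasibility).
CONSTRAINT_TOL = 1e-6

#: Floating-point dust absorbed by post-convergence clamping in fcls mode.
CLAMP_TOL = 1e-9


def _design_matrix(lib: EndmemberLibrary, band_valid=None):
    """Endmember matrix restricted to valid bands, (B_valid, K), with checks."""
    valid = lib.band_valid if band_valid is None else band_valid
    E = lib.spectra[:, valid].T  # (B, K)
    if E.shape[0] < lib.n_classes:
        raise DataError(
            f"{lib.n_classes} endmembers require more than {E.shape[0]} valid bands"
        )
    s = np.linalg.svd(E, compute_uv=False)
    if s[-1] < RANK_TOL * s[0]:
        # name the closest pair so the user can fix the library
        worst, names = np.inf, (lib.class_names[0], lib.class_names[-1])
        for i, j in itertools.combinations(range(lib.n_classes), 2):
            si, sj = E[:, i], E[:, j]
            denom = np.linalg.norm(si) * np.linalg.norm(sj)
            ang = np.arccos(np.clip(si @ sj / denom, -1.0, 1.0)) if denom else 0.0
            if ang < worst:
                worst, names = ang, (lib.class_names[i], lib.class_names[j])
        raise CollinearEndmembersError(names)
    return E


def _solve_sto(E, r, support):
    """Equality-constrained LS on a support set: min ||E_S a - r||, sum a = 1."""
    Es = E[:, support]
    k = Es.shape[1]
    G = Es.T @ Es
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * Es.T @ r, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
        raise NumericalError("singular KKT system in sum-to-one solve") from exc
    return sol[:k], sol[k]  # fractions on support, multiplier lambda


def _fcls_active_set(E, r, max_iter=200):
    """Exact simplex-constrained least squares by active-set iteration.

    Maintains a support set of strictly positive fractions; at each step the
    sum-to-one equality problem is solved on the support, the most negative
    component (if any) is clamped to zero, and clamped components whose KKT
    multiplier turns negative are readmitted.
    """
    k = E.shape[1]
    support = list(range(k))
    a = np.zeros(k)
    for _ in range(max_iter):
        a_s, lam = _solve_sto(E, r, support)
        if a_s.min() < -CONSTRAINT_TOL:
            drop = support[int(np.argmin(a_s))]
            support.remove(drop)
            if not support:  # pragma: no cover - impossible with sum-to-one
                raise NumericalError("active set emptied during fcls solve")
            continue
        a = np.zeros(k)
        a[support] = np.clip(a_s, 0.0, None)
        # dual feasibility of clamped components: mu_j = g_j + lambda >= 0
        grad = 2.0 * E.T @ (E @ a - r)
        inactive = [j for j in range(k) if j not in support]
        if not inactive:
            return a
        mu = grad[inactive] + lam
        worst = int(np.argmin(mu))
        if mu[worst] >= -CONSTRAINT_TOL:
            return a
        support.append(inactive[worst])
        support.sort()
    raise NumericalError("fcls active-set iteration did not converge")


def unmix_pixel(r, lib: EndmemberLibrary, mode: str = "fcls", band_valid=None):
    """Solve the mixing model for one pixel spectrum.

    Parameters
    ----------
    r : ndarray, shape (B,)
        Pixel reflectance on the library's full band axis.
    lib : EndmemberLibrary
    mode : {"ols", "sto", "nnls", "fcls"}
    band_valid : ndarray of bool, optional
        Overrides the library's valid-band mask.

    Returns
    -------
    fractions : ndarray, shape (K,)
    rmse : float
        Root-mean-square reconstruction residual over the valid bands.
    """
    if mode not in MODES:
        raise DataError(f"unknown constraint mode {mode!r}; choose from {MODES}")
    r = np.asarray(r, dtype=np.float64)
    valid = lib.band_valid if band_valid is None else np.asarray(band_valid, bool)
    if r.shape != (valid.size,):
        raise DataError("pixel spectrum does not match the library band axis")
    E = _design_matrix(lib, valid)
    rv = r[valid]
    a = _solve_modes(E, rv, mode)
    resid = E @ a - rv
    rmse = float(np.sqrt(np.mean(resid**2)))
    return a, rmse


def _solve_modes(E, rv, mode):
    if mode == "ols":
        a, *_ = np.linalg.lstsq(E, rv, rcond=None)
    elif mode == "sto":
        a, _ = _solve_sto(E, rv, list(range(E.shape[1])))
    elif mode == "nnls":
        a, _ = scipy.optimize.nnls(E, rv)
    else:  # fcls
        a = _fcls_active_set(E, rv)
        # absorb floating-point dust only; real violations raise below
        a = np.clip(a, 0.0, 1.0)
        if abs(a.sum() - 1.0) > CONSTRAINT_TOL:
            raise NumericalError(
                f"fcls solution violates sum-to-one by {abs(a.sum() - 1.0):.2e}"
            )
        a /= a.sum()
    return a


def unmix_cube(
    cube: SpectralCube, lib: EndmemberLibrary, mode: str = "fcls"
) -> FractionStack:
    """Unmix every valid pixel of a cube into a FractionStack.

    Invalid pixels propagate as invalid (fractions NaN). The sum-to-one
    first-pass solution is computed for all pixels at once; only pixels
    whose unconstrained-simplex solution leaves the feasible region fall
    back to the per-pixel active-set solver, which keeps whole-cube fcls
    runs fast.
    """
    if mode not in MODES:
        raise DataError(f"unknown constraint mode {mode!r}; choose from {MODES}")
    if cube.n_bands != lib.n_bands or not np.allclose(
        cube.wavelengths_nm, lib.wavelengths_nm
    ):
        raise DataError("cube and library band axes differ")
    valid_bands = cube.band_valid & lib.band_valid
    E = _design_matrix(lib, valid_bands)
    k = lib.n_classes
    rows, cols, _ = cube.shape
    flat_valid = cube.pixel_valid.ravel()
    R = cube.reflectance.reshape(rows * cols, -1)[:, valid_bands]
    fractions = np.full((rows * cols, k), np.nan)
    rmse = np.full(rows * cols, np.nan)

    idx = np.flatnonzero(flat_valid)
    if idx.size:
        Rv = R[idx]
        if mode in ("sto", "fcls"):
            A = _vectorized_sto(E, Rv)
            if mode == "fcls":
                bad = np.flatnonzero(A.min(axis=1) < -CONSTRAINT_TOL)
                for j in bad:
                    A[j] = _fcls_active_set(E, Rv[j])
                A = np.clip(A, 0.0, 1.0)
                A /= A.sum(axis=1, keepdims=True)
        elif mode == "ols":
            A, *_ = np.linalg.lstsq(E, Rv.T, rcond=None)
            A = A.T
        else:  # nnls has no vectorized form
            A = np.empty((idx.size, k))
            for j in range(idx.size):
                A[j], _ = scipy.optimize.nnls(E, Rv[j])
        resid = Rv - A @ E.T
        fractions[idx] = A
        rmse[idx] = np.sqrt(np.mean(resid**2, axis=1))

    return FractionStack(
        fractions=fractions.T.reshape(k, rows, cols),
        class_names=list(lib.class_names),
        residual_rmse=rmse.reshape(rows, cols),
        mode=mode,
        pixel_valid=cube.pixel_valid.copy(),
        pixel_size_m=cube.pixel_size_m,
        origin_xy=tuple(cube.origin_xy),
        crs_label=cube.crs_label,
    )


def _vectorized_sto(E, Rv):
    """Sum-to-one LS for many pixels at once (shared KKT factorisation)."""
    k = E.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * (E.T @ E)
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.empty((k + 1, Rv.shape[0]))
    rhs[:k] = 2.0 * E.T @ Rv.T
    rhs[k] = 1.0
    sol = np.linalg.solve(kkt, rhs)
    return sol[:k].T  # (n_pixels, K)


def simplex_lattice(k: int, step: float) -> np.ndarray:
    """All points of the unit simplex lattice with spacing ``step``."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise DataError("1/step must be an integer")
    pts = []
    for combo in itertools.combinations(range(m + k - 1), k - 1):
        # stars and bars: gaps between bars are the lattice coordinates
        prev, coords = -1, []
        for c in combo:
            coords.append(c - prev - 1)
            prev = c
        coords.append(m + k - 2 - prev)
        pts.append(coords)
    return np.asarray(pts, dtype=np.float64) * step


def brute_force_unmix(r, lib: EndmemberLibrary, step: float = 0.01, band_valid=None):
    """Exhaustive fully-constrained unmixing over a simplex lattice.

    A test oracle, not a production solver: enumerates every abundance
    vector on the simplex lattice of spacing ``step`` and returns the one
    minimising the residual. Guarded to K <= 4.
    """
    if lib.n_classes > 4:
        raise DataError("brute-force search is limited to K <= 4")
    r = np.asarray(r, dtype=np.float64)
    valid = lib.band_valid if band_valid is None else np.asarray(band_valid, bool)
    E = lib.spectra[:, valid].T
    rv = r[valid]
    lattice = simplex_lattice(lib.n_classes, step)
    resid = lattice @ E.T - rv  # (L, B)
    best = int(np.argmin(np.einsum("ij,ij->i", resid, resid)))
    return lattice[best]
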