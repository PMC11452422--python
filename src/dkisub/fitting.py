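"""DKI model estimation: weighted least squares and positivity-constrained fits.

The DKI signal representation per volume (b, n) is

    ln S = ln S0 − b·D_app(n) + (b²/6)·MD²·K_app(n),

linear in 22 coefficients: the log-baseline, the 6 unique diffusion-tensor
components D_ij, and 15 kurtosis-block coefficients that equal MD²·W_ijkl
(the regression stays linear; the dimensionless kurtosis tensor W is
recovered at metric-derivation time by dividing by the fitted MD²).

``fit_wls`` is the classical two-pass weighted least squares on
log-signals: an OLS pass provides predicted signals whose squares serve as
weights (the standard heteroscedasticity correction for log-transformed
Rician-limited magnitudes).  ``fit_constrained`` minimizes the same
objective subject to K_app(nᵢ) ≥ 0 for every acquired diffusion direction —
a convex inequality-constrained quadratic program solved exactly in its
dual form as a least-distance problem via Lawson–Hanson NNLS after Cholesky
whitening.  Batched variants vectorize over many single-voxel datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import nnls

from .scheme import GradientScheme, IllPosedSchemeError
from .substrate import SignalDataset

__all__ = [
    "DKIFitResult",
    "build_design_matrix",
    "constraint_matrix",
    "fit_wls",
    "fit_constrained",
    "fit_batch",
    "apparent_values",
]

# component orders (fixed API contract)
DT_COMPONENTS = ["xx", "yy", "zz", "xy", "xz", "yz"]
_DT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_DT_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

KT_COMPONENTS = [
    "xxxx", "yyyy", "zzzz",
    "xxxy", "xxxz", "xyyy", "yyyz", "xzzz", "yzzz",
    "xxyy", "xxzz", "yyzz",
    "xxyz", "xyyz", "xyzz",
]
_KT_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2),
    (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_KT_MULT = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0,
                     6.0, 6.0, 6.0, 12.0, 12.0, 12.0])

SIGNAL_FLOOR = 1e-10  # relative to s0, applied before taking logs
CONSTRAINT_TOL = 1e-10


def quadratic_form_design(directions: np.ndarray) -> np.ndarray:
    """(V, 6) rows such that row·dt = nᵀDn (multiplicities included)."""
    n = np.atleast_2d(directions)
    cols = [n[:, i] * n[:, j] for (i, j) in _DT_IDX]
    return np.column_stack(cols) * _DT_MULT


def quartic_form_design(directions: np.ndarray) -> np.ndarray:
    """(V, 15) rows such that row·kt = Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ (multiplicities included)."""
    n = np.atleast_2d(directions)
    cols = [n[:, i] * n[:, j] * n[:, k] * n[:, l] for (i, j, k, l) in _KT_IDX]
    return np.column_stack(cols) * _KT_MULT


@dataclass(frozen=True)
class DKIFitResult:
    """Fitted DKI coefficients for one voxel/instance.

    ``kt_raw`` stores the linear regression coefficients MD²·W; the
    dimensionless kurtosis-tensor components are exposed as ``kt``.
    """

    log_s0: float
    dt: np.ndarray  # (6,) xx, yy, zz, xy, xz, yz in mm²/s
    kt_raw: np.ndarray  # (15,) MD²·W components, (mm²/s)²
    convergence_flag: str = "ok"  # ok | constrained_active | failed

    @property
    def tensor(self) -> np.ndarray:
        """Reconstructed symmetric 3×3 diffusion tensor."""
        d = np.empty((3, 3))
        for c, (i, j) in zip(self.dt, _DT_IDX):
            d[i, j] = d[j, i] = c
        return d

    @property
    def md(self) -> float:
        return float(self.dt[:3].sum() / 3.0)

    @property
    def kt(self) -> np.ndarray:
        """Dimensionless kurtosis-tensor components W = kt_raw / MD²."""
        return self.kt_raw / self.md**2

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.log_s0], self.dt, self.kt_raw])

    @classmethod
    def from_coefficients(cls, x: np.ndarray, flag: str = "ok") -> "DKIFitResult":
        return cls(log_s0=float(x[0]), dt=np.array(x[1:7]),
                   kt_raw=np.array(x[7:22]), convergence_flag=flag)


def build_design_matrix(scheme: GradientScheme, check_rank: bool = True) -> np.ndarray:
    """(N, 22) design matrix mapping coefficients to log-signals."""
    if scheme.n_volumes < 22:
        raise IllPosedSchemeError("need at least 22 volumes for a DKI fit")
    a = np.zeros((scheme.n_volumes, 22))
    a[:, 0] = 1.0
    dw = scheme.dw_mask
    n = scheme.directions[dw]
    b = scheme.bvalues[dw]
    a[dw, 1:7] = -b[:, None] * quadratic_form_design(n)
    a[dw, 7:22] = (b**2 / 6.0)[:, None] * quartic_form_design(n)
    if check_rank and np.linalg.matrix_rank(a) < 22:
        raise IllPosedSchemeError("scheme does not span the 22 DKI coefficients")
    return a


def constraint_matrix(scheme: GradientScheme, n_sphere: int = 60) -> np.ndarray:
    """Rows g such that g·x ≥ 0 ⇔ K_app(n) ≥ 0 along constraint directions.

    Restricting *all* apparent directional kurtosis to positive values is
    approximated by constraining every acquired diffusion direction plus
    ``n_sphere`` quasi-uniform sphere directions (pass 0 for
    acquired-directions-only).
    """
    from .sphere import fibonacci_sphere

    dw = scheme.dw_mask
    dirs = scheme.directions[dw]
    if n_sphere:
        dirs = np.vstack([dirs, fibonacci_sphere(n_sphere)])
    g = np.zeros((len(dirs), 22))
    g[:, 7:22] = quartic_form_design(dirs)
    return g


# ---------------------------------------------------------------------------
# Solvers


def _ldp_nnls(e: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Least-distance problem: min ‖y‖ s.t. e @ y ≥ h (Lawson–Hanson).

    Returns y, or None when infeasible.
    """
    m, dim = e.shape
    a = np.vstack([e.T, h[None, :]])  # (dim+1, m)
    b = np.zeros(dim + 1)
    b[dim] = 1.0
    u, _ = nnls(a, b)
    r = a @ u - b
    denom = r[dim]
    if abs(denom) < 1e-12:
        return None
    return -r[:dim] / denom


def _solve_constrained(h_mat: np.ndarray, f: np.ndarray, g: np.ndarray):
    """min ½xᵀHx − fᵀx s.t. Gx ≥ 0, via Cholesky whitening + LDP."""
    low = np.linalg.cholesky(h_mat)
    c = solve_triangular(low, f, lower=True)
    e = solve_triangular(low, g.T, lower=True).T  # G L⁻ᵀ
    y = _ldp_nnls(e, -e @ c)
    if y is None:
        return None
    z = y + c
    return solve_triangular(low.T, z, lower=False)


def fit_batch(
    signals: np.ndarray,
    scheme: GradientScheme,
    constrained: bool = True,
    s0: float = 1.0,
    design: np.ndarray | None = None,
    chunk: int = 512,
):
    """Fit many single-voxel datasets sharing one scheme.

    Parameters
    ----------
    signals : (M, N) array of amplitudes.
    constrained : apply the K_app ≥ 0 constraints where the unconstrained
        WLS solution violates them.

    Returns
    -------
    coeffs : (M, 22) coefficient array.
    flags : (M,) array of strings (``ok``/``constrained_active``/``failed``).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    a = build_design_matrix(scheme) if design is None else design
    y = np.log(np.maximum(signals, SIGNAL_FLOOR * s0))
    pinv = np.linalg.pinv(a)
    x_ols = y @ pinv.T  # (M, 22)
    m = len(y)
    coeffs = np.empty((m, 22))
    flags = np.full(m, "ok", dtype=object)
    g = constraint_matrix(scheme) if constrained else None
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        w = np.exp(2.0 * (x_ols[sl] @ a.T))  # predicted-signal-squared weights
        h_all = np.einsum("mn,ni,nj->mij", w, a, a, optimize=True)
        f_all = (w * y[sl]) @ a
        try:
            x = np.linalg.solve(h_all, f_all[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            x = np.full((h_all.shape[0], 22), np.nan)
            for i in range(h_all.shape[0]):
                try:
                    x[i] = np.linalg.solve(h_all[i], f_all[i])
                except np.linalg.LinAlgError:
                    flags[start + i] = "failed"
        coeffs[sl] = x
        if constrained:
            viol = (x @ g.T).min(axis=1) < -CONSTRAINT_TOL
            for i in np.flatnonzero(viol):
                xc = _solve_constrained(h_all[i], f_all[i], g)
                idx = start + i
                if xc is None:
                    flags[idx] = "failed"
                else:
                    coeffs[idx] = xc
                    flags[idx] = "constrained_active"
    bad = ~np.isfinite(coeffs).all(axis=1)
    flags[bad] = "failed"
    return coeffs, flags


def _fit_single(data: SignalDataset, constrained: bool) -> DKIFitResult:
    coeffs, flags = fit_batch(
        data.signals[None, :], data.scheme, constrained=constrained, s0=data.s0
    )
    return DKIFitResult.from_coefficients(coeffs[0], flag=str(flags[0]))


def fit_wls(data: SignalDataset) -> DKIFitResult:
    """Unconstrained two-pass weighted least squares fit."""
    return _fit_single(data, constrained=False)


def fit_constrained(data: SignalDataset) -> DKIFitResult:
    """WLS fit with apparent kurtosis restricted to non-negative values
    along every acquired diffusion direction."""
    return _fit_single(data, constrained=True)


def apparent_values(fit: DKIFitResult, direction, b: float = None):
    """(D_app, K_app) of a fit along one unit direction.

    The b-value does not enter the apparent values themselves; the argument
    is accepted for call-site symmetry with acquisition volumes.
    """
    n = np.asarray(direction, dtype=float)
    d_app = float(quadratic_form_design(n[None, :])[0] @ fit.dt)
    if d_app <= 0:
        raise ValueError("non-positive apparent diffusivity: kurtosis undefined")
    k_app = float(quartic_form_design(n[None, :])[0] @ fit.kt_raw) / d_app**2
    return d_app, k_app
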