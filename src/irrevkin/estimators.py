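"""Estimators for irreversible-tracer kinetics.

* Basis-function linearization of the irreversible 2TCM with plasma input
  (fixed or estimated fractional blood volume): per-θ weighted linear solve
  via QR, WRSS-minimizing θ selected from a log-spaced grid.
* Patlak graphical analysis (slope after equilibration time t*).
* Weighted nonlinear least-squares reference fit of the full model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import FrameSchedule, RateConstants, SampledCurve, TissueTAC
from .kinetics import DEFAULT_GRID_STEP, TacModel

__all__ = [
    "BasisSet",
    "FitResult",
    "FitConfig",
    "build_basis",
    "fit_bafpic_fixed_vb",
    "fit_bafpic_variable_vb",
    "fit_patlak",
    "fit_2tcmi_nls",
    "fit_tac",
]

_RANK_TOL = 1e-10


@dataclass
class FitResult:
    """Result of one TAC fit, whatever the estimator.

    φ1 and φ2 are the linear coefficients of the basis-function model:
    φ1 = (1-VB)·K1·k3/θ multiplies ∫Ca, φ2 = (1-VB)·K1·k2/θ multiplies the
    selected basis curve.  Rate constants are recovered as
    K1 = (φ1+φ2)/(1-VB), k2 = φ2·θ/(φ1+φ2), k3 = φ1·θ/(φ1+φ2),
    Ki = φ1/(1-VB).
    """

    method: str
    phi1: float = np.nan
    phi2: float = np.nan
    theta_hat: float = np.nan
    vb_hat: float = np.nan
    K1: float = np.nan
    k2: float = np.nan
    k3: float = np.nan
    Ki: float = np.nan
    lambda_k3: float = np.nan
    wrss: float = np.nan
    flag: str | None = None
    patlak_intercept: float | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "phi1": self.phi1,
            "phi2": self.phi2,
            "theta_hat": self.theta_hat,
            "vb_hat": self.vb_hat,
            "K1": self.K1,
            "k2": self.k2,
            "k3": self.k3,
            "Ki": self.Ki,
            "lambda_k3": self.lambda_k3,
            "wrss": self.wrss,
            "flag": self.flag,
        }


@dataclass
class FitConfig:
    """Estimator configuration shared by the Monte Carlo engine and the CLI."""

    method: str = "bafpic_fixed"  # bafpic_fixed | bafpic_variable | patlak | nls
    theta_min: float = 0.06  # min⁻¹, slow-frequency cutoff
    theta_max: float = 3.0  # min⁻¹
    n_basis: int = 50
    vb_value: float = 0.05
    tstar: float = 27.25  # min, Patlak equilibration time
    weights: str = "model"  # model | uniform

    def __post_init__(self) -> None:
        valid = {"bafpic_fixed", "bafpic_variable", "patlak", "nls"}
        if self.method not in valid:
            raise ValueError(f"method must be one of {sorted(valid)}")


def _normalize_weights(weights: np.ndarray | None, n_frames: int) -> np.ndarray:
    if weights is None:
        w = np.full(n_frames, 1.0 / n_frames)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_frames,):
            raise ValueError("weights must have one entry per frame")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        w = w / total
    return w


@dataclass
class BasisSet:
    """Log-spaced θ grid with frame-averaged basis curves and precomputed
    QR factorizations of the weighted designs.

    ``Qt2``/``Rinv2`` factorize the two-column design [∫Ca, BF_j] used when
    VB is fixed; ``Qt3``/``Rinv3`` factorize [∫Ca, BF_j, Cb] used when VB is
    estimated.  Weighted rows are pre-scaled by sqrt(w).
    """

    thetas: np.ndarray
    schedule: FrameSchedule
    int_ca: np.ndarray  # frame-averaged ∫Ca
    cb_frames: np.ndarray  # frame-averaged Cb
    ca_frames: np.ndarray  # frame-averaged Ca (Patlak reuse)
    basis_curves: np.ndarray  # (n, F) frame-averaged BF_j
    weights: np.ndarray  # normalized, sums to 1
    sw: np.ndarray = field(repr=False, default=None)
    Xw2: np.ndarray = field(repr=False, default=None)
    Qt2: np.ndarray = field(repr=False, default=None)
    Rinv2: np.ndarray = field(repr=False, default=None)
    Xw3: np.ndarray = field(repr=False, default=None)
    Qt3: np.ndarray = field(repr=False, default=None)
    Rinv3: np.ndarray = field(repr=False, default=None)
    valid3: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return int(self.thetas.size)

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames


def _stack_qr(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Economic QR of each (F, k) design in a (n, F, k) stack."""
    n, F, k = X.shape
    Qt = np.empty((n, k, F))
    Rinv = np.empty((n, k, k))
    valid = np.ones(n, dtype=bool)
    for j in range(n):
        Q, R = np.linalg.qr(X[j])
        diag = np.abs(np.diag(R))
        scale = diag.max() if diag.max() > 0 else 1.0
        if np.any(diag < _RANK_TOL * scale):
            valid[j] = False
            Qt[j] = 0.0
            Rinv[j] = 0.0
            continue
        Qt[j] = Q.T
        Rinv[j] = np.linalg.inv(R)
    return Qt, Rinv, valid


def build_basis(
    ca: SampledCurve,
    cb: SampledCurve,
    schedule: FrameSchedule,
    theta_min: float = 0.06,
    theta_max: float = 3.0,
    n: int = 50,
    weights: np.ndarray | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    sampling: str = "average",
    thetas: np.ndarray | None = None,
) -> BasisSet:
    """Build the θ grid and pre-factorize the weighted designs.

    θ values are logarithmically spaced on [theta_min, theta_max], both
    endpoints included.  An explicit ``thetas`` array overrides the spacing
    (used e.g. to place the true θ on the grid in oracle tests).
    """
    if thetas is None:
        if not (0 < theta_min < theta_max):
            raise ValueError("need 0 < theta_min < theta_max")
        if n < 2:
            raise ValueError("need n >= 2 basis members")
        thetas = np.geomspace(theta_min, theta_max, n)
    else:
        thetas = np.asarray(thetas, dtype=float)
        if thetas.size < 2 or np.any(np.diff(thetas) <= 0) or thetas[0] <= 0:
            raise ValueError("explicit thetas must be positive and increasing")

    model = TacModel(ca, cb, schedule, grid_step=grid_step, sampling=sampling)
    F = schedule.n_frames
    w = _normalize_weights(weights, F)
    sw = np.sqrt(w)

    bf = np.empty((thetas.size, F))
    for j, th in enumerate(thetas):
        bf[j] = model.basis_frames(th)

    X2 = np.empty((thetas.size, F, 2))
    X2[:, :, 0] = model.int_ca_frames
    X2[:, :, 1] = bf
    Xw2 = X2 * sw[None, :, None]
    Qt2, Rinv2, _ = _stack_qr(Xw2)

    X3 = np.empty((thetas.size, F, 3))
    X3[:, :, :2] = X2
    X3[:, :, 2] = model.cb_frames
    Xw3 = X3 * sw[None, :, None]
    Qt3, Rinv3, valid3 = _stack_qr(Xw3)

    return BasisSet(
        thetas=thetas,
        schedule=schedule,
        int_ca=model.int_ca_frames,
        cb_frames=model.cb_frames,
        ca_frames=model.ca_frames,
        basis_curves=bf,
        weights=w,
        sw=sw,
        Xw2=Xw2,
        Qt2=Qt2,
        Rinv2=Rinv2,
        Xw3=Xw3,
        Qt3=Qt3,
        Rinv3=Rinv3,
        valid3=valid3,
    )


def _solve_all_thetas(
    yw: np.ndarray, Xw: np.ndarray, Qt: np.ndarray, Rinv: np.ndarray,
    valid: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-θ weighted LS coefficients and WRSS for one weighted data vector."""
    qty = Qt @ yw  # (n, k)
    beta = np.einsum("nij,nj->ni", Rinv, qty)
    fitted = np.einsum("nfk,nk->nf", Xw, beta)
    resid = yw[None, :] - fitted
    wrss = np.einsum("nf,nf->n", resid, resid)
    if valid is not None:
        wrss = np.where(valid, wrss, np.inf)
    return beta, wrss


def _derive_from_phis(
    phi1: float, phi2: float, theta: float, vb: float
) -> tuple[float, float, float, float, float]:
    one_m_vb = 1.0 - vb
    s = phi1 + phi2
    K1 = s / one_m_vb
    Ki = phi1 / one_m_vb
    if s != 0.0:
        k2 = phi2 * theta / s
        k3 = phi1 * theta / s
    else:
        k2 = np.nan
        k3 = np.nan
    if np.isfinite(k2) and k2 != 0.0:
        lam = (K1 / k2) * k3
    else:
        lam = np.nan
    return K1, k2, k3, Ki, lam


def fit_bafpic_fixed_vb(tac: TissueTAC, basis: BasisSet, vb: float) -> FitResult:
    """Basis-function fit with the vascular signal subtracted at a fixed VB.

    vb·Cb is removed from the TAC, then for each θ_j the two-coefficient
    weighted least-squares problem is solved; the θ_j with minimal WRSS wins
    (ties: smallest θ).
    """
    if not (0 <= vb < 1):
        raise ValueError("vb must lie in [0, 1)")
    if tac.schedule.n_frames != basis.n_frames:
        raise ValueError("TAC and basis were built on different schedules")
    y = tac.values - vb * basis.cb_frames
    if np.max(np.abs(y)) == 0.0:
        return FitResult(
            method="bafpic_fixed",
            phi1=0.0,
            phi2=0.0,
            theta_hat=float(basis.thetas[0]),
            vb_hat=vb,
            K1=0.0,
            k2=np.nan,
            k3=np.nan,
            Ki=0.0,
            lambda_k3=np.nan,
            wrss=0.0,
            flag="degenerate",
        )
    yw = basis.sw * y
    beta, wrss = _solve_all_thetas(yw, basis.Xw2, basis.Qt2, basis.Rinv2, None)
    j = int(np.argmin(wrss))
    phi1, phi2 = float(beta[j, 0]), float(beta[j, 1])
    theta = float(basis.thetas[j])
    K1, k2, k3, Ki, lam = _derive_from_phis(phi1, phi2, theta, vb)
    return FitResult(
        method="bafpic_fixed",
        phi1=phi1,
        phi2=phi2,
        theta_hat=theta,
        vb_hat=vb,
        K1=K1,
        k2=k2,
        k3=k3,
        Ki=Ki,
        lambda_k3=lam,
        wrss=float(wrss[j]),
    )


def fit_bafpic_variable_vb(tac: TissueTAC, basis: BasisSet) -> FitResult:
    """Basis-function fit with VB estimated as a third linear coefficient."""
    if tac.schedule.n_frames != basis.n_frames:
        raise ValueError("TAC and basis were built on different schedules")
    y = tac.values
    if np.max(np.abs(y)) == 0.0:
        return FitResult(
            method="bafpic_var",
            phi1=0.0,
            phi2=0.0,
            theta_hat=float(basis.thetas[0]),
            vb_hat=0.0,
            K1=0.0,
            k2=np.nan,
            k3=np.nan,
            Ki=0.0,
            lambda_k3=np.nan,
            wrss=0.0,
            flag="degenerate",
        )
    yw = basis.sw * y
    beta, wrss = _solve_all_thetas(
        yw, basis.Xw3, basis.Qt3, basis.Rinv3, basis.valid3
    )
    if not np.any(np.isfinite(wrss)):
        return FitResult(method="bafpic_var", flag="rank_deficient")
    j = int(np.argmin(wrss))
    phi1, phi2, vb_hat = (float(b) for b in beta[j])
    theta = float(basis.thetas[j])
    K1, k2, k3, Ki, lam = _derive_from_phis(phi1, phi2, theta, vb_hat)
    flag = None if basis.valid3.all() else "some_thetas_skipped"
    return FitResult(
        method="bafpic_var",
        phi1=phi1,
        phi2=phi2,
        theta_hat=theta,
        vb_hat=vb_hat,
        K1=K1,
        k2=k2,
        k3=k3,
        Ki=Ki,
        lambda_k3=lam,
        wrss=float(wrss[j]),
        flag=flag,
    )


def fit_patlak(
    tac: TissueTAC,
    ca: SampledCurve,
    cb: SampledCurve,
    tstar: float = 27.25,
    vb: float = 0.05,
    grid_step: float = DEFAULT_GRID_STEP,
    sampling: str = "average",
) -> FitResult:
    """Patlak graphical analysis of an irreversible tracer.

    Ordinary least-squares slope of y = (CT - vb·Cb)/Ca against
    x = ∫Ca/Ca over frames with midpoint >= t*.  The slope of the
    vascular-corrected plot estimates (1-vb)·Ki, so the reported Ki is
    slope/(1-vb), putting all estimators on the same scale.
    """
    if not (0 <= vb < 1):
        raise ValueError("vb must lie in [0, 1)")
    model = TacModel(ca, cb, tac.schedule, grid_step=grid_step, sampling=sampling)
    sel = tac.schedule.midpoints >= tstar
    if int(sel.sum()) < 3:
        raise ValueError("Patlak needs at least 3 frames with midpoint >= t*")
    ca_f = model.ca_frames[sel]
    if np.any(ca_f <= 0):
        raise ValueError("frame-averaged Ca must be positive after t*")
    x = model.int_ca_frames[sel] / ca_f
    y = (tac.values[sel] - vb * model.cb_frames[sel]) / ca_f
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ki = float(slope) / (1.0 - vb)
    return FitResult(
        method="patlak",
        Ki=ki,
        vb_hat=vb,
        wrss=float(resid @ resid),
        patlak_intercept=float(intercept),
    )


_NLS_BASE = np.array([0.3, 0.1, 0.05])
_NLS_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)
_NLS_LOWER = np.array([0.0, 0.0, 0.0])
_NLS_UPPER = np.array([2.0, 1.0, 1.0])


def fit_2tcmi_nls(
    tac: TissueTAC,
    ca: SampledCurve,
    cb: SampledCurve,
    vb: float = 0.05,
    weights: np.ndarray | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    sampling: str = "average",
) -> FitResult:
    """Weighted trust-region nonlinear least squares of the full model.

    (K1, k2, k3) are estimated with VB fixed; five multiplicative restarts
    around a physiological gray-matter start mitigate local minima.
    """
    if not (0 <= vb < 1):
        raise ValueError("vb must lie in [0, 1)")
    model = TacModel(ca, cb, tac.schedule, grid_step=grid_step, sampling=sampling)
    w = _normalize_weights(weights, tac.schedule.n_frames)
    sw = np.sqrt(w)
    y = tac.values - vb * model.cb_frames
    one_m_vb = 1.0 - vb

    def residuals(p):
        return sw * (one_m_vb * model.tissue_frames(*p) - y)

    best = None
    for scale in _NLS_SCALES:
        x0 = np.clip(_NLS_BASE * scale, _NLS_LOWER + 1e-6, _NLS_UPPER - 1e-6)
        try:
            sol = least_squares(
                residuals, x0, bounds=(_NLS_LOWER, _NLS_UPPER), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return FitResult(method="nls", flag="no_convergence")
    K1, k2, k3 = (float(v) for v in best.x)
    theta = k2 + k3
    ki = K1 * k3 / theta if theta > 0 else 0.0
    lam = (K1 / k2) * k3 if k2 > 0 else np.nan
    phi1 = one_m_vb * K1 * k3 / theta if theta > 0 else 0.0
    phi2 = one_m_vb * K1 * k2 / theta if theta > 0 else 0.0
    return FitResult(
        method="nls",
        phi1=phi1,
        phi2=phi2,
        theta_hat=theta,
        vb_hat=vb,
        K1=K1,
        k2=k2,
        k3=k3,
        Ki=ki,
        lambda_k3=lam,
        wrss=float(2.0 * best.cost),
    )


def fit_tac(
    tac: TissueTAC,
    ca: SampledCurve,
    cb: SampledCurve,
    config: FitConfig,
    basis: BasisSet | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Dispatch a single-TAC fit according to a :class:`FitConfig`."""
    if config.method in ("bafpic_fixed", "bafpic_variable"):
        if basis is None:
            basis = build_basis(
                ca, cb, tac.schedule,
                theta_min=config.theta_min, theta_max=config.theta_max,
                n=config.n_basis, weights=weights,
            )
        if config.method == "bafpic_fixed":
            return fit_bafpic_fixed_vb(tac, basis, config.vb_value)
        return fit_bafpic_variable_vb(tac, basis)
    if config.method == "patlak":
        return fit_patlak(tac, ca, cb, tstar=config.tstar, vb=config.vb_value)
    return fit_2tcmi_nls(tac, ca, cb, vb=config.vb_value, weights=weights)
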