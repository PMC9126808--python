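"""Case-control region tests: burden score test, SKAT and SKAT-O.

The replication-stage engine for unrelated cohorts.  A logistic null model
with covariates (sequencing center, age, sex, ancestry PCs) is fitted
once; each window is then tested with score statistics:

    burden:  U = c'(y − μ̂), c = Gw;   U²/Var(U) ~ χ²₁
    SKAT:    Q = Σ_v (w_v g_v'(y − μ̂))² ~ Σ_j λ_j χ²₁

with Var(U) = c'P₀c and λ_j the eigenvalues of (GW)'P₀(GW), where
P₀ = V − VX(X'VX)⁻¹X'V is the score-variance projection.  Mixture-of-
chi-square tails use the modified Liu moment-matching approximation by
default, with an Imhof-type characteristic-function integration available
for higher accuracy.  SKAT-O scans Q_ρ = (1−ρ)Q_SKAT + ρQ_burden over a
ρ grid and combines the minimum p via the one-dimensional integral of the
optimal-test construction.

The SKAT small-sample moment adjustment for n < 2000 is not implemented;
a :class:`SmallSampleWarning` is emitted instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, ncx2

from .io import GenotypeMatrix
from .windows import Window

__all__ = [
    "CCTestConfig",
    "NullModel",
    "CCRegionResult",
    "SmallSampleWarning",
    "SeparationError",
    "fit_null",
    "burden_test",
    "skat_test",
    "skato_test",
    "build_design",
    "scan_case_control",
    "mixture_chi2_sf",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class SmallSampleWarning(UserWarning):
    """Cohort below the size where the omitted small-sample moment
    adjustment would matter most."""


class SeparationError(ValueError):
    """Perfect or quasi-perfect separation in the logistic null fit."""


@dataclass
class CCTestConfig:
    weight_scheme: str = "flat"  # or "beta" for Beta(AF; 1, 25)
    tail_method: str = "liu"  # or "integration" (Imhof)
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    n_pcs: int = 4

    def __post_init__(self) -> None:
        if self.weight_scheme not in ("flat", "beta"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.tail_method not in ("liu", "integration"):
            raise ValueError(f"unknown tail method {self.tail_method!r}")


@dataclass
class NullModel:
    """Fitted logistic null with the projection pieces for score tests."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    mu: np.ndarray
    v: np.ndarray  # working variances μ(1−μ)

    def __post_init__(self) -> None:
        self.resid = self.y - self.mu
        self._VX = self.X * self.v[:, None]
        self._XtVX = self.X.T @ self._VX

    def adjust(self, M: np.ndarray) -> np.ndarray:
        """Return Z = (I − H)V^{1/2}M so that Z'Z = M'P₀M."""
        M = np.atleast_2d(M.T).T if M.ndim == 1 else M
        sv = np.sqrt(self.v)
        XtVM = self.X.T @ (self.v[:, None] * M)
        return sv[:, None] * M - (sv[:, None] * self.X) @ np.linalg.solve(
            self._XtVX, XtVM
        )


# ---------------------------------------------------------------------------
# Null model fit
# ---------------------------------------------------------------------------

def fit_null(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> NullModel:
    """Maximum-likelihood logistic fit of phenotype on covariates.

    Raises on a constant phenotype, rank-deficient design, or (quasi-)
    perfect separation (the error names the most implicated covariate).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("design and phenotype lengths differ")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; cannot fit a null model")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient covariate design (rank {rank} < {X.shape[1]})")
    if y.size < 2000:
        warnings.warn(
            f"n = {y.size} < 2000: the SKAT small-sample moment adjustment "
            "is not implemented; tail approximations may be slightly "
            "anti-conservative in very small cohorts",
            SmallSampleWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-8)
    mu = np.asarray(res.fittedvalues)
    eps = 1e-8
    if mu.min() < eps or mu.max() > 1 - eps:
        coefs = np.abs(res.params * X.std(axis=0))
        worst = names[int(np.argmax(coefs))]
        raise SeparationError(
            f"perfect separation in the null model (covariate {worst!r})"
        )
    return NullModel(X=X, y=y, names=list(names), mu=mu, v=mu * (1 - mu))


# ---------------------------------------------------------------------------
# Mixture-of-chi-square tails
# ---------------------------------------------------------------------------

def _liu_params(lam: np.ndarray) -> tuple[float, float, float, float, float, float]:
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        df = a**2 - 2 * d
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        d = 0.0
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    mu_x = df + d
    sigma_x = np.sqrt(2) * np.sqrt(df + 2 * d)
    return mu_q, sigma_q, mu_x, sigma_x, df, d


def _liu_sf(q: float, lam: np.ndarray) -> float:
    mu_q, sigma_q, mu_x, sigma_x, df, d = _liu_params(lam)
    q_norm = (q - mu_q) / sigma_q * sigma_x + mu_x
    if d > 0:
        return float(ncx2.sf(q_norm, df, d))
    return float(chi2.sf(q_norm, df))


def _liu_quantile(p_upper: float, lam: np.ndarray) -> float:
    """Value q with approximate P(Σλχ² > q) = p_upper (Liu scale)."""
    mu_q, sigma_q, mu_x, sigma_x, df, d = _liu_params(lam)
    if d > 0:
        t = ncx2.isf(p_upper, df, d)
    else:
        t = chi2.isf(p_upper, df)
    return (t - mu_x) / sigma_x * sigma_q + mu_q


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """P(Σ λ_j χ²₁ > q) by numerical inversion of the characteristic
    function (Imhof's integral)."""
    lam = np.asarray(lam, dtype=float)

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400, epsabs=1e-12, epsrel=1e-9)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def mixture_chi2_sf(q: float, lam: np.ndarray, method: str = "liu") -> float:
    """Upper tail of Σ λ_j χ²₁ at q."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > max(1e-12, 1e-10 * lam.sum() if lam.size else 0)]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(chi2.sf(q / lam[0], 1))
    if method == "integration":
        return _imhof_sf(q, lam)
    return _liu_sf(q, lam)


# ---------------------------------------------------------------------------
# Region tests
# ---------------------------------------------------------------------------

def _window_weights(G_window: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "flat":
        return np.ones(G_window.shape[1])
    af = np.clip(np.nanmean(G_window, axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return beta_dist.pdf(af, 1, 25)


def burden_test(
    null: NullModel, G_window: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Collapse the window into c = Gw and score-test it: χ²₁ p-value."""
    G_window = np.atleast_2d(G_window)
    if G_window.shape[1] == 0:
        raise ValueError("empty window")
    if weights is None:
        weights = np.ones(G_window.shape[1])
    c = G_window @ weights
    U = float(c @ null.resid)
    z = null.adjust(c[:, None])
    var = float((z * z).sum())
    if var <= 1e-12:
        return 1.0
    return float(chi2.sf(U**2 / var, 1))


def skat_test(
    null: NullModel,
    G_window: np.ndarray,
    weights: np.ndarray | None = None,
    method: str = "liu",
) -> float:
    """Variance-component score test; mixture-of-chi-square p-value."""
    G_window = np.atleast_2d(G_window)
    if G_window.shape[1] == 0:
        raise ValueError("empty window")
    if weights is None:
        weights = np.ones(G_window.shape[1])
    u = (G_window.T @ null.resid) * weights
    Q = float(u @ u)
    Z1 = null.adjust(G_window * weights[None, :])
    lam = np.linalg.eigvalsh(Z1.T @ Z1)
    return mixture_chi2_sf(Q, lam, method)


@dataclass
class CCRegionResult:
    window: str
    n_variants: int
    p_burden: float
    p_skat: float
    p_skato: float
    rho_grid: tuple[float, ...]
    p_rho: tuple[float, ...]
    fallback: bool = False


def _rho_half(rho: float, V: int) -> np.ndarray:
    """Symmetric square root of R_ρ = (1−ρ)I + ρ11'."""
    ones = np.ones((V, V)) / V
    e_top = 1 - rho + V * rho
    e_rest = 1 - rho
    return np.sqrt(e_top) * ones + np.sqrt(e_rest) * (np.eye(V) - ones)


def skato_test(
    null: NullModel,
    G_window: np.ndarray,
    weights: np.ndarray | None = None,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
    method: str = "liu",
    window_id: str = "",
) -> CCRegionResult:
    """Optimal unified test over Q_ρ = (1−ρ)Q_SKAT + ρQ_burden.

    Per-ρ p-values use the mixture approximation; the minimum over the
    grid is combined by integrating over the shared burden-direction
    chi-square factor.  If the integration fails, the Bonferroni bound
    grid-size × min-p is reported with ``fallback=True``.
    """
    G_window = np.atleast_2d(G_window)
    V = G_window.shape[1]
    if V == 0:
        raise ValueError("empty window")
    if weights is None:
        weights = np.ones(V)
    p_b = burden_test(null, G_window, weights)
    p_s = skat_test(null, G_window, weights, method)
    if V == 1 or np.ptp(G_window) == 0:
        # rank-1 window: every rho is the same test
        return CCRegionResult(
            window_id, V, p_b, p_s, p_s, tuple(rho_grid), tuple([p_s] * len(rho_grid))
        )

    u = (G_window.T @ null.resid) * weights
    Q_skat = float(u @ u)
    Q_burden = float(u.sum() ** 2)
    Z1 = null.adjust(G_window * weights[None, :])
    A = Z1.T @ Z1

    p_rho = []
    lam_rho = []
    for rho in rho_grid:
        Rh = _rho_half(rho, V)
        lam = np.linalg.eigvalsh(Rh @ A @ Rh)
        lam_rho.append(lam)
        Q_r = (1 - rho) * Q_skat + rho * Q_burden
        if rho == 1.0:
            p_rho.append(p_b)
        elif rho == 0.0:
            p_rho.append(p_s)
        else:
            p_rho.append(mixture_chi2_sf(Q_r, lam, method))
    pmin = float(min(p_rho))
    if pmin >= 1.0:
        return CCRegionResult(
            window_id, V, p_b, p_s, 1.0, tuple(rho_grid), tuple(p_rho)
        )

    # ---- combined p for the min-p statistic (optimal-test construction) --
    fallback = False
    try:
        zbar = Z1.mean(axis=1)
        zbar2 = float(zbar @ zbar)
        if zbar2 <= 1e-14:
            raise FloatingPointError("degenerate burden direction")
        cof = (zbar @ Z1) / zbar2
        Z_rem = Z1 - np.outer(zbar, cof)
        M_rem = Z_rem.T @ Z_rem
        lam_cond = np.linalg.eigvalsh(M_rem)
        lam_cond = lam_cond[lam_cond > 1e-10 * max(1.0, lam_cond.max())]
        mu_q = float(lam_cond.sum())
        var_remain = 4.0 * float(np.sum(np.outer(cof, cof) * zbar2 * M_rem))
        var_q = 2.0 * float(np.sum(lam_cond**2)) + var_remain
        sd_ratio = np.sqrt(max(var_q - var_remain, 1e-300)) / np.sqrt(var_q)
        rho_eff = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
        tau = (V**2 * rho_eff + (1 - rho_eff) * float(np.sum(cof**2))) * zbar2
        q_rho = np.array(
            [_liu_quantile(pmin, lam) for lam in lam_rho]
        )

        def integrand(x: float) -> float:
            bound = np.min((q_rho - tau * x) / (1 - rho_eff))
            if bound <= 0:
                return 0.0
            if lam_cond.size == 0:
                surv = 0.0
            else:
                b_adj = (bound - mu_q) * sd_ratio + mu_q
                surv = mixture_chi2_sf(b_adj, lam_cond, method)
            return (1.0 - surv) * chi2.pdf(x, 1)

        val, _ = integrate.quad(
            integrand, 0, chi2.isf(1e-12, 1), limit=200, epsabs=1e-14, epsrel=1e-6
        )
        p_skato = 1.0 - val
    except Exception:
        fallback = True
        p_skato = min(1.0, len(rho_grid) * pmin)
        warnings.warn(
            f"SKAT-O integration failed for window {window_id!r}; "
            "reporting the Bonferroni bound",
            stacklevel=2,
        )
    p_skato = float(np.clip(p_skato, pmin, min(1.0, len(rho_grid) * pmin)))
    return CCRegionResult(
        window_id, V, p_b, p_s, p_skato, tuple(rho_grid), tuple(p_rho), fallback
    )


# ---------------------------------------------------------------------------
# Design construction and genome scan
# ---------------------------------------------------------------------------

def build_design(
    covariates: pd.DataFrame, samples: list[str], n_pcs: int = 4
) -> tuple[np.ndarray, list[str]]:
    """Intercept + center dummies + age + sex + PC1..PCk design matrix.

    Uses whichever of the columns ``center``, ``age``, ``sex``, ``PC*``
    are present, aligned to the sample order.
    """
    cov = covariates.loc[samples]
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    if "center" in cov.columns:
        dummies = pd.get_dummies(cov["center"], prefix="center", drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for c in ("age", "sex"):
        if c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(c)
    pc_cols = sorted(
        (c for c in cov.columns if c.startswith("PC") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )[:n_pcs]
    for c in pc_cols:
        cols.append(cov[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def scan_case_control(
    G: GenotypeMatrix,
    phenotypes: pd.Series,
    covariates: pd.DataFrame | None,
    windows: list[Window],
    cfg: CCTestConfig | None = None,
) -> pd.DataFrame:
    """Burden / SKAT / SKAT-O over every window for an unrelated cohort.

    Missing dosages are mean-imputed per variant.  The null model is
    fitted once across the cohort.
    """
    cfg = cfg or CCTestConfig()
    y = phenotypes.loc[G.samples].to_numpy(dtype=float)
    if covariates is not None:
        X, names = build_design(covariates, G.samples, cfg.n_pcs)
    else:
        X, names = np.ones((len(y), 1)), ["intercept"]
    null = fit_null(y, X, names)

    dosage = G.dosage.copy()
    if np.isnan(dosage).any():
        col_mean = np.nanmean(dosage, axis=0)
        col_mean = np.nan_to_num(col_mean)
        nan_r, nan_c = np.where(np.isnan(dosage))
        dosage[nan_r, nan_c] = col_mean[nan_c]

    rows = []
    for win in windows:
        cols = np.asarray(win.variant_idx, dtype=int)
        Gw = dosage[:, cols]
        weights = _window_weights(Gw, cfg.weight_scheme)
        try:
            res = skato_test(
                null, Gw, weights, cfg.rho_grid, cfg.tail_method, win.wid
            )
            rows.append(
                {
                    "window": win.wid,
                    "chrom": win.chrom,
                    "first_snv": win.first_key,
                    "last_snv": win.last_key,
                    "n_variants": win.size,
                    "p_burden": res.p_burden,
                    "p_skat": res.p_skat,
                    "p_skato": res.p_skato,
                    "fallback": res.fallback,
                    "error": "",
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "window": win.wid,
                    "chrom": win.chrom,
                    "first_snv": win.first_key,
                    "last_snv": win.last_key,
                    "n_variants": win.size,
                    "p_burden": np.nan,
                    "p_skat": np.nan,
                    "p_skato": np.nan,
                    "fallback": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
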