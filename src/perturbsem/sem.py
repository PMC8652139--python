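"""Three-node path model: two correlated exogenous regulators, one reporter.

The model of interest is

    endpoint = gamma11 * fac1 + gamma21 * fac2 + e,   e ~ N(0, psi)

with (fac1, fac2) jointly normal with free variances and (optionally free)
covariance.  Fitting is maximum likelihood on the covariance structure: the
estimates minimise the discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - log|S| - 3

where S is the sample covariance with divisor n-1, and the test statistic is
T = (n-1) * F_min, asymptotically chi-square with df = 6 - #free parameters.

Every constraint pattern of this model (any subset of {gamma11, gamma21,
exo covariance} fixed to zero) admits an exact closed-form minimiser,
because F separates into an exogenous-block term and a conditional
regression term; the solution is a (restricted) regression identity.  No
iterative optimisation is needed.

Fit quality is summarised by the usual global indices — RMSEA with a 90%
confidence interval from noncentral chi-square inversion, CFI and TLI
against the independence baseline, and SRMR — with the conventional
rules of thumb (RMSEA < 0.05 close fit, CFI/TLI = 1 perfect, SRMR < 0.08
very good fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEMData",
    "PathModelSpec",
    "PathModel",
    "PathModelResults",
    "fit_path_model",
    "baseline_model",
    "fit_indices",
    "rmsea_ci",
    "implied_covariance",
    "discrepancy",
    "render_model_figure",
]

_RANK_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """The covariance-structure optimisation failed to produce a valid fit."""


@dataclass
class SEMData:
    """Samples x 3 dataset: two regressor variables and one reporter."""

    fac1: np.ndarray
    fac2: np.ndarray
    endpoint: np.ndarray

    def __post_init__(self) -> None:
        self.fac1 = np.asarray(self.fac1, dtype=float).ravel()
        self.fac2 = np.asarray(self.fac2, dtype=float).ravel()
        self.endpoint = np.asarray(self.endpoint, dtype=float).ravel()
        if not (len(self.fac1) == len(self.fac2) == len(self.endpoint)):
            raise ValueError("fac1, fac2 and endpoint must have equal length")
        if self.n < 4:
            raise ValueError(f"need at least 4 samples, got {self.n}")
        if not np.isfinite(self.as_matrix()).all():
            raise ValueError("non-finite values in SEM data")

    @property
    def n(self) -> int:
        return len(self.endpoint)

    def as_matrix(self) -> np.ndarray:
        """n x 3 array in (fac1, fac2, endpoint) order."""
        return np.column_stack([self.fac1, self.fac2, self.endpoint])


@dataclass(frozen=True)
class PathModelSpec:
    """Which parameters of the 3-node model are free (True) vs fixed to 0."""

    free_gamma11: bool = True
    free_gamma21: bool = True
    free_exo_covariance: bool = True

    def __post_init__(self) -> None:
        if not (self.free_gamma11 or self.free_gamma21):
            raise ValueError("at least one regression path must be free")

    @property
    def n_free(self) -> int:
        # three variances always free
        return 3 + self.free_gamma11 + self.free_gamma21 + self.free_exo_covariance

    @property
    def df_model(self) -> int:
        return 6 - self.n_free


SATURATED = PathModelSpec()


def implied_covariance(
    var_fac1: float,
    var_fac2: float,
    exo_cov: float,
    gamma11: float,
    gamma21: float,
    resid_var: float,
) -> np.ndarray:
    """Model-implied 3x3 covariance in (fac1, fac2, endpoint) order."""
    phi = np.array([[var_fac1, exo_cov], [exo_cov, var_fac2]])
    gamma = np.array([gamma11, gamma21])
    sxy = phi @ gamma
    syy = gamma @ phi @ gamma + resid_var
    out = np.empty((3, 3))
    out[:2, :2] = phi
    out[:2, 2] = sxy
    out[2, :2] = sxy
    out[2, 2] = syy
    return out


def discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML covariance-structure discrepancy F(S, Sigma)."""
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ConvergenceError("implied covariance is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - S.shape[0])


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def baseline_model(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence baseline: diagonal implied covariance, free variances.

    The ML solution is Sigma = diag(S), giving chisq_b = -(n-1) log|R| with
    R the sample correlation matrix; df_b = 3 for three variables.
    """
    S = np.asarray(S, dtype=float)
    chisq_b = (n - 1) * discrepancy(S, np.diag(np.diag(S)))
    return float(max(chisq_b, 0.0)), 3


def _ncx2_cdf(x: float, df: int, nc: float) -> float:
    if nc <= 0:
        return float(stats.chi2.cdf(x, df))
    return float(stats.ncx2.cdf(x, df, nc))


def rmsea_ci(
    chisq: float, df: int, n: int, level: float = 0.90, tol: float = 1e-8
) -> tuple[float, float]:
    """RMSEA confidence interval by noncentral chi-square inversion.

    The lower (upper) endpoint is sqrt(lambda / (df (n-1))) where lambda
    makes the noncentral chi-square CDF at the observed statistic equal to
    (1+level)/2 (respectively (1-level)/2); lambda is truncated at zero and
    found by bisection to ``tol``.
    """
    if df == 0:
        return (0.0, 0.0)
    upper_p = (1.0 + level) / 2.0  # 0.95 for a 90% interval
    lower_p = (1.0 - level) / 2.0  # 0.05

    def _solve(target: float) -> float:
        # CDF decreases in the noncentrality; nc=0 gives the maximum
        if _ncx2_cdf(chisq, df, 0.0) <= target:
            return 0.0
        lo, hi = 0.0, max(chisq, 1.0)
        while _ncx2_cdf(chisq, df, hi) > target:
            hi *= 2.0
            if hi > 1e10:  # pragma: no cover - pathological input
                break
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _ncx2_cdf(chisq, df, mid) > target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lam_lo = _solve(upper_p)
    lam_hi = _solve(lower_p)
    scale = df * (n - 1)
    return (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))


def fit_indices(
    chisq: float,
    df_model: int,
    chisq_b: float,
    df_b: int,
    n: int,
    S: np.ndarray,
    sigma_hat: np.ndarray,
) -> tuple[float, tuple[float, float], float, float, float]:
    """RMSEA (with 90% CI), CFI, TLI and SRMR from the fitted model.

    SRMR averages the squared standardised residuals over all 6 unique
    elements of S - Sigma_hat, diagonals included, each residual scaled by
    the product of the corresponding sample standard deviations.
    """
    S = np.asarray(S, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    excess = max(chisq - df_model, 0.0)

    if df_model == 0:
        # saturated: T is zero up to round-off; perfect fit by convention
        rmsea, ci, cfi, tli = 0.0, (0.0, 0.0), 1.0, 1.0
    else:
        rmsea = float(np.sqrt(excess / (df_model * (n - 1))))
        ci = rmsea_ci(chisq, df_model, n)
        denom = max(chisq_b - df_b, excess, 0.0)
        cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
        base_ratio = chisq_b / df_b
        tli = (base_ratio - chisq / df_model) / (base_ratio - 1.0)

    sd = np.sqrt(np.diag(S))
    std_resid = (S - sigma_hat) / np.outer(sd, sd)
    iu = np.triu_indices(3)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    return rmsea, ci, float(cfi), float(tli), srmr


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

_PARAM_ORDER = ["var_fac1", "var_fac2", "exo_cov", "gamma11", "gamma21", "resid_var"]


class PathModel:
    """The 3-node path model, built from data plus a constraint pattern.

    Parameters
    ----------
    data
        An :class:`SEMData`, or anything accepted by its constructor fields
        via :meth:`from_dataframe` / the (fac1, fac2, endpoint) keyword form.
    spec
        Which parameters are free; default all free (saturated model).
    """

    def __init__(self, data: SEMData, spec: PathModelSpec = SATURATED):
        if not isinstance(data, SEMData):
            raise TypeError("data must be an SEMData; see PathModel.from_dataframe")
        self.data = data
        self.spec = spec
        X = data.as_matrix()
        self.S = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.linalg.eigvalsh(self.S)
        if eigvals[0] <= _RANK_TOL * max(eigvals[-1], 1.0):
            raise np.linalg.LinAlgError(
                "sample covariance matrix is singular (collinear or constant variables)"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fac1: str,
        fac2: str,
        endpoint: str,
        spec: PathModelSpec = SATURATED,
    ) -> "PathModel":
        """Build the model from named columns of a samples x variables table."""
        data = SEMData(df[fac1].to_numpy(), df[fac2].to_numpy(), df[endpoint].to_numpy())
        return cls(data, spec)

    # -- estimation --------------------------------------------------------

    def _closed_form_estimates(self) -> dict[str, float]:
        """Exact ML minimiser of the discrepancy under the constraint pattern.

        F separates into an exogenous-block term (minimised by S_xx, or its
        diagonal when the covariance is fixed to 0) and a conditional term
        log psi + (s_yy - 2 g's_xy + g'S_xx g)/psi whose minimiser over the
        free gammas is the restricted regression solution.
        """
        S = self.S
        spec = self.spec
        s_xx = S[:2, :2]
        s_xy = S[:2, 2]
        s_yy = S[2, 2]

        free_idx = [i for i, f in enumerate((spec.free_gamma11, spec.free_gamma21)) if f]
        gamma = np.zeros(2)
        if free_idx:
            A = s_xx[np.ix_(free_idx, free_idx)]
            b = s_xy[free_idx]
            gamma[free_idx] = np.linalg.solve(A, b)
        psi = float(s_yy - 2 * gamma @ s_xy + gamma @ s_xx @ gamma)
        psi = max(psi, 0.0)
        exo_cov = float(s_xx[0, 1]) if spec.free_exo_covariance else 0.0
        return {
            "var_fac1": float(s_xx[0, 0]),
            "var_fac2": float(s_xx[1, 1]),
            "exo_cov": exo_cov,
            "gamma11": float(gamma[0]),
            "gamma21": float(gamma[1]),
            "resid_var": psi,
        }

    def _free_names(self) -> list[str]:
        names = ["var_fac1", "var_fac2"]
        if self.spec.free_exo_covariance:
            names.append("exo_cov")
        if self.spec.free_gamma11:
            names.append("gamma11")
        if self.spec.free_gamma21:
            names.append("gamma21")
        names.append("resid_var")
        return names

    def _delta_matrices(self, est: dict[str, float]) -> dict[str, np.ndarray]:
        """Analytic derivatives d Sigma / d theta_j at the estimate."""
        gamma = np.array([est["gamma11"], est["gamma21"]])
        phi = np.array(
            [[est["var_fac1"], est["exo_cov"]], [est["exo_cov"], est["var_fac2"]]]
        )
        deltas: dict[str, np.ndarray] = {}

        def _phi_delta(a: int, b: int) -> np.ndarray:
            X = np.zeros((2, 2))
            X[a, b] = 1.0
            X[b, a] = 1.0
            D = np.zeros((3, 3))
            D[:2, :2] = X
            D[:2, 2] = X @ gamma
            D[2, :2] = X @ gamma
            D[2, 2] = gamma @ X @ gamma
            return D

        deltas["var_fac1"] = _phi_delta(0, 0)
        deltas["var_fac2"] = _phi_delta(1, 1)
        deltas["exo_cov"] = _phi_delta(0, 1)

        for j, name in enumerate(("gamma11", "gamma21")):
            e = np.zeros(2)
            e[j] = 1.0
            D = np.zeros((3, 3))
            col = phi @ e
            D[:2, 2] = col
            D[2, :2] = col
            D[2, 2] = 2.0 * (phi @ gamma)[j]
            deltas[name] = D

        D = np.zeros((3, 3))
        D[2, 2] = 1.0
        deltas["resid_var"] = D
        return deltas

    def fit(self) -> "PathModelResults":
        """Maximum-likelihood fit; returns a :class:`PathModelResults`."""
        est = self._closed_form_estimates()
        sigma_hat = implied_covariance(**est)
        try:
            f_min = discrepancy(self.S, sigma_hat)
        except ConvergenceError:
            raise ConvergenceError(
                "implied covariance at the ML solution is singular "
                "(residual variance collapsed to zero)"
            ) from None
        n = self.data.n
        chisq = max((n - 1) * f_min, 0.0)

        # expected-information standard errors
        free = self._free_names()
        deltas = self._delta_matrices(est)
        sigma_inv = np.linalg.inv(sigma_hat)
        k = len(free)
        info = np.empty((k, k))
        for i in range(k):
            Ai = sigma_inv @ deltas[free[i]]
            for j in range(i, k):
                info[i, j] = info[j, i] = 0.5 * (n - 1) * np.trace(
                    Ai @ sigma_inv @ deltas[free[j]]
                )
        try:
            cov_params = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from None
        bse = {name: float(np.sqrt(max(cov_params[i, i], 0.0))) for i, name in enumerate(free)}

        chisq_b, df_b = baseline_model(self.S, n)
        df_model = self.spec.df_model
        rmsea, ci, cfi, tli, srmr = fit_indices(
            chisq, df_model, chisq_b, df_b, n, self.S, sigma_hat
        )
        chisq_p = float(stats.chi2.sf(chisq, df_model)) if df_model > 0 else 1.0

        return PathModelResults(
            model=self,
            params=est,
            free_names=free,
            bse=bse,
            cov_params=pd.DataFrame(cov_params, index=free, columns=free),
            chisq=float(chisq),
            df_model=df_model,
            chisq_pvalue=chisq_p,
            chisq_baseline=chisq_b,
            df_baseline=df_b,
            n=n,
            rmsea=rmsea,
            rmsea_ci90=ci,
            cfi=cfi,
            tli=tli,
            srmr=srmr,
            sample_cov=self.S,
            implied_cov=sigma_hat,
        )


@dataclass
class PathModelResults:
    """Estimates, uncertainties and global fit indices of a fitted path model."""

    model: PathModel
    params: dict[str, float]
    free_names: list[str]
    bse: dict[str, float]
    cov_params: pd.DataFrame
    chisq: float
    df_model: int
    chisq_pvalue: float
    chisq_baseline: float
    df_baseline: int
    n: int
    rmsea: float
    rmsea_ci90: tuple[float, float]
    cfi: float
    tli: float
    srmr: float
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    zvalues: dict[str, float] = field(init=False)
    pvalues: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.zvalues = {}
        self.pvalues = {}
        for name in self.free_names:
            se = self.bse[name]
            z = self.params[name] / se if se > 0 else np.inf * np.sign(self.params[name] or 1)
            self.zvalues[name] = float(z)
            self.pvalues[name] = float(2.0 * stats.norm.sf(abs(z)))

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["params"][name]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def standardized_gammas(self) -> dict[str, float]:
        """Path coefficients on the correlation scale (per-SD units)."""
        sd = np.sqrt(np.diag(self.sample_cov))
        return {
            "gamma11": self.params["gamma11"] * sd[0] / sd[2],
            "gamma21": self.params["gamma21"] * sd[1] / sd[2],
        }

    def statistic(self, name: str) -> float:
        """Look up a scalar summary by name (for bootstrap selectors)."""
        scalars = {
            "chisq": self.chisq,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "tli": self.tli,
            "srmr": self.srmr,
            **self.params,
        }
        try:
            return float(scalars[name])
        except KeyError:
            raise KeyError(
                f"unknown statistic {name!r}; choose from {sorted(scalars)}"
            ) from None

    def to_dict(self) -> dict[str, float]:
        """Flat key-value report (JSON-serialisable)."""
        out: dict[str, float] = dict(self.params)
        for name in self.free_names:
            out[f"se_{name}"] = self.bse[name]
            out[f"z_{name}"] = self.zvalues[name]
            out[f"p_{name}"] = self.pvalues[name]
        std = self.standardized_gammas
        out.update(
            std_gamma11=std["gamma11"],
            std_gamma21=std["gamma21"],
            chisq=self.chisq,
            df_model=self.df_model,
            chisq_pvalue=self.chisq_pvalue,
            chisq_baseline=self.chisq_baseline,
            df_baseline=self.df_baseline,
            n=self.n,
            rmsea=self.rmsea,
            rmsea_ci90_lo=self.rmsea_ci90[0],
            rmsea_ci90_hi=self.rmsea_ci90[1],
            cfi=self.cfi,
            tli=self.tli,
            srmr=self.srmr,
        )
        return out

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "3-node path model (maximum likelihood, covariance structure)",
            f"  n = {self.n}   free parameters = {len(self.free_names)}   "
            f"df = {self.df_model}",
            f"  chi-square = {self.chisq:.4f}  (p = {self.chisq_pvalue:.4f})",
            "",
            f"  {'parameter':<12}{'estimate':>12}{'std err':>12}{'z':>10}{'P>|z|':>10}",
        ]
        for name in _PARAM_ORDER:
            est = self.params[name]
            if name in self.free_names:
                lines.append(
                    f"  {name:<12}{est:>12.4f}{self.bse[name]:>12.4f}"
                    f"{self.zvalues[name]:>10.3f}{self.pvalues[name]:>10.4f}"
                )
            else:
                lines.append(f"  {name:<12}{est:>12.4f}{'(fixed)':>12}")
        std = self.standardized_gammas
        lines += [
            "",
            f"  standardized: gamma11 = {std['gamma11']:.4f}, "
            f"gamma21 = {std['gamma21']:.4f}",
            f"  RMSEA = {self.rmsea:.4f}  90% CI [{self.rmsea_ci90[0]:.4f}, "
            f"{self.rmsea_ci90[1]:.4f}]",
            f"  CFI = {self.cfi:.4f}   TLI = {self.tli:.4f}   SRMR = {self.srmr:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, path) -> None:
        render_model_figure(self, path)


def fit_path_model(data: SEMData, spec: PathModelSpec = SATURATED) -> PathModelResults:
    """Functional wrapper: fit the 3-node path model and return its results."""
    return PathModel(data, spec).fit()


# ---------------------------------------------------------------------------
# figure
# ---------------------------------------------------------------------------


def render_model_figure(fit: PathModelResults, path) -> None:
    """Draw the 3-node diagram (SVG/PNG by file extension).

    Nodes for the two regulators and the reporter; one directed edge per
    free path labelled with the estimate and significance stars; a
    two-headed arc for a free exogenous covariance.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import FancyArrowPatch

    spec = fit.model.spec
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.set_xlim(0, 10)
    ax.set_ylim(0, 10)
    ax.axis("off")

    pos = {"fac1": (2, 7.5), "fac2": (2, 2.5), "endpoint": (8, 5)}
    for name, (x, y) in pos.items():
        ax.add_patch(plt.Circle((x, y), 1.15, fill=True, fc="#eef3fb", ec="black"))
        ax.text(x, y, name, ha="center", va="center", fontsize=11)

    def _stars(p: float) -> str:
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    def _edge(src: str, pname: str, label_dy: float) -> None:
        est = fit.params[pname]
        sig = _stars(fit.pvalues[pname]) if pname in fit.pvalues else ""
        arrow = FancyArrowPatch(
            pos[src], pos["endpoint"], arrowstyle="-|>", mutation_scale=18,
            shrinkA=24, shrinkB=24, color="black",
        )
        arrow.set_gid(f"path_{pname}")
        ax.add_patch(arrow)
        mx = (pos[src][0] + pos["endpoint"][0]) / 2
        my = (pos[src][1] + pos["endpoint"][1]) / 2 + label_dy
        ax.text(mx, my, f"{pname} = {est:.3f}{sig}", ha="center", fontsize=9)

    if spec.free_gamma11:
        _edge("fac1", "gamma11", 0.7)
    if spec.free_gamma21:
        _edge("fac2", "gamma21", -0.7)
    if spec.free_exo_covariance:
        arc = FancyArrowPatch(
            pos["fac1"], pos["fac2"], arrowstyle="<|-|>", mutation_scale=14,
            shrinkA=24, shrinkB=24, connectionstyle="arc3,rad=0.45", color="gray",
        )
        arc.set_gid("exo_covariance")
        ax.add_patch(arc)
        ax.text(0.6, 5, f"cov = {fit.params['exo_cov']:.3f}", fontsize=9, rotation=90,
                va="center")
    ax.text(
        5, 0.4,
        f"chi2({fit.df_model}) = {fit.chisq:.3f}   RMSEA = {fit.rmsea:.3f}   "
        f"CFI = {fit.cfi:.3f}",
        ha="center", fontsize=9,
    )
    fig.savefig(path)
    plt.close(fig)
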