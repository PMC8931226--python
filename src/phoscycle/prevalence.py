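"""Completeness-corrected trait prevalence and beta-binomial regression.

Partial single-cell assemblies systematically under-count trait
carriers: a cassette on a dropped contig is invisible. With per-genome
assembly length g_i, completeness c_i and detected cassette span p_i
(0 for apparent non-carriers), the corrected per-clade prevalence is

    (sum_i p_i / sum_i g_i) * sum_i (g_i / c_i) * (1 / p_bar) * (1 / n)

where p_bar is the mean cassette span over detected carriers and n the
number of assemblies. With c_i = 1 everywhere this reduces exactly to
the naive carrier fraction.

Trait-fraction regressions use a beta-binomial likelihood with a logit
link on the mean: counts y_i out of m_i genomes with
E[y_i/m_i] = mu_i = logistic(x_i' beta) and intra-class correlation
rho = phi / (1 + phi). Per-observation beta parameters follow the
a_i = mu_i / phi, b_i = (1 - mu_i) / phi convention, so phi -> 0
recovers the binomial. phi is optimized on the log scale (log link on
rho/(1-rho) = phi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .models import TraitCall


@dataclass
class PrevalenceInput:
    """Per-clade (p_i, g_i, c_i) records feeding the corrected formula."""

    clade: str
    p: np.ndarray  # operon span per genome, bp (0 for non-producers)
    g: np.ndarray  # assembly length, bp
    c: np.ndarray  # completeness in (0, 1]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (len(self.p) == len(self.g) == len(self.c)):
            raise ValueError("p, g, c must have equal length")
        if np.any(self.p < 0):
            raise ValueError("operon lengths must be >= 0")
        if np.any((self.c <= 0) | (self.c > 1)):
            raise ValueError("completeness must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.p)

    @property
    def p_bar(self) -> float:
        producers = self.p[self.p > 0]
        return float(producers.mean()) if len(producers) else 0.0


def corrected_prevalence(
    inp: PrevalenceInput, p_bar_override: float | None = None
) -> dict:
    """Completeness-corrected producer prevalence for one clade.

    Returns the corrected estimate, the naive carrier fraction, and a
    flag when the corrected estimate is undefined (no carriers) or
    exceeds 1 (the estimator is unbounded; values above 1 are reported
    as-is, not clipped).
    """
    if inp.n == 0:
        raise ValueError("empty input")
    if inp.g.sum() <= 0:
        raise ValueError("total assembly length must be positive")
    naive = float((inp.p > 0).mean())
    p_bar = p_bar_override if p_bar_override is not None else inp.p_bar
    if p_bar <= 0:
        return {
            "clade": inp.clade,
            "corrected": 0.0,
            "naive": naive,
            "p_bar": 0.0,
            "n": inp.n,
            "undefined": True,
            "above_one": False,
        }
    corrected = (
        (inp.p.sum() / inp.g.sum())
        * (inp.g / inp.c).sum()
        * (1.0 / p_bar)
        * (1.0 / inp.n)
    )
    return {
        "clade": inp.clade,
        "corrected": float(corrected),
        "naive": naive,
        "p_bar": float(p_bar),
        "n": inp.n,
        "undefined": False,
        "above_one": bool(corrected > 1.0),
    }


def recovery_corrected_fractions(
    calls: list[TraitCall],
    meta: pd.DataFrame,
    min_completeness: float = 0.0,
) -> pd.DataFrame:
    """Per-clade naive and corrected producer proportions.

    ``meta`` must carry genome_id, clade, completeness, assembly_length.
    Clades with fewer than two producers fall back to the global mean
    operon span (with a warning); clades with zero members are omitted.
    ``min_completeness`` optionally drops low-completeness assemblies
    (default keeps everything).
    """
    meta = meta.set_index("genome_id")
    by_id = {c.genome_id: c for c in calls}
    rows = []
    for gid in meta.index:
        if gid not in by_id:
            raise ValueError(f"no trait call for genome {gid}")
        if meta.loc[gid, "completeness"] < min_completeness:
            continue
        c = by_id[gid]
        rows.append(
            {
                "genome_id": gid,
                "clade": meta.loc[gid, "clade"],
                "p": c.operon_length_bp if c.is_producer else 0.0,
                "g": meta.loc[gid, "assembly_length"],
                "c": meta.loc[gid, "completeness"],
            }
        )
    df = pd.DataFrame(rows)
    all_spans = df.loc[df.p > 0, "p"]
    global_p_bar = float(all_spans.mean()) if len(all_spans) else 0.0

    out = []
    for clade, sub in df.groupby("clade"):
        inp = PrevalenceInput(
            clade=str(clade), p=sub.p.values, g=sub.g.values, c=sub.c.values
        )
        override = None
        if (sub.p > 0).sum() < 2 and global_p_bar > 0:
            warnings.warn(
                f"clade {clade}: <2 producers; using global mean operon span",
                stacklevel=2,
            )
            override = global_p_bar
        out.append(corrected_prevalence(inp, p_bar_override=override))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Beta-binomial regression


@dataclass
class BetaBinomModel:
    """Design for a beta-binomial trait-count regression."""

    X: np.ndarray  # samples x covariates, intercept included
    y: np.ndarray  # trait counts
    m: np.ndarray  # totals
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] == 0 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one row per observation")
        if np.any((self.y < 0) | (self.y > self.m)):
            raise ValueError("counts must satisfy 0 <= y <= m")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]


@dataclass
class BetaBinomFit:
    names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    phi: float
    log_likelihood: float
    df: int
    resid_df: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str) -> dict:
        if name not in self.names:
            raise KeyError(f"unknown covariate {name!r}")
        j = self.names.index(name)
        return {
            "Est": float(self.estimates[j]),
            "Err": float(self.std_errors[j]),
            "t": float(self.t_values[j]),
            "P": float(self.p_values[j]),
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Est": self.estimates,
                "Err": self.std_errors,
                "t": self.t_values,
                "P": self.p_values,
            },
            index=self.names,
        )


_LOG_PHI_FLOOR = -30.0  # phi below ~1e-13 is numerically binomial


def _bb_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray, m: np.ndarray) -> float:
    beta, log_phi = theta[:-1], theta[-1]
    eta = np.clip(X @ beta, -30, 30)
    mu = special.expit(eta)
    phi = np.exp(log_phi)
    if log_phi <= _LOG_PHI_FLOOR:
        # binomial limit
        ll = y * np.log(mu) + (m - y) * np.log1p(-mu)
    else:
        a = mu / phi
        b = (1.0 - mu) / phi
        ll = (
            special.betaln(y + a, m - y + b)
            - special.betaln(a, b)
        )
    ll = ll + special.gammaln(m + 1) - special.gammaln(y + 1) - special.gammaln(m - y + 1)
    return float(np.sum(ll))


def _logistic_warm_start(X: np.ndarray, y: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Newton-Raphson logistic fit on proportions as the warm start."""
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        mu = special.expit(np.clip(X @ beta, -30, 30))
        W = m * mu * (1 - mu) + 1e-10
        grad = X.T @ (y - m * mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_betabinom(model: BetaBinomModel, fix_phi: float | None = None) -> BetaBinomFit:
    """Maximum-likelihood beta-binomial regression fit.

    Quasi-Newton (BFGS) from a logistic warm start with jittered
    restarts. The boundary phi -> 0 (binomial limit) is always evaluated
    as a candidate, since the log-link parameterization cannot reach it;
    the higher-likelihood solution wins. ``fix_phi`` pins the dispersion
    (0 fits the binomial submodel). Standard errors come from the
    inverse observed information (numerical Hessian); two-sided p-values
    from the t distribution on residual degrees of freedom
    (n - estimated parameters, dispersion included when free).
    """
    X, y, m = model.X, model.y, model.m
    flags: list[str] = []
    if np.all((y == 0) | (y == m)):
        flags.append("separation")
    beta0 = _logistic_warm_start(X, y, m)
    if np.max(np.abs(beta0)) > 25:
        flags.append("separation")
    k = X.shape[1]

    def nll(theta):
        return -_bb_loglik(theta, X, y, m)

    def optimize_beta(log_phi: float, start: np.ndarray):
        """Profile fit of beta at fixed dispersion."""
        f = lambda b: -_bb_loglik(np.concatenate([b, [log_phi]]), X, y, m)
        return optimize.minimize(f, start, method="BFGS",
                                 options={"gtol": 1e-9, "maxiter": 500})

    if fix_phi is not None:
        if fix_phi < 0:
            raise ValueError("fix_phi must be >= 0")
        log_phi = np.log(fix_phi) if fix_phi > 0 else _LOG_PHI_FLOOR
        res = optimize_beta(log_phi, beta0)
        theta = np.concatenate([res.x, [log_phi]])
        best_fun = res.fun
        converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-4)
        phi_free = False
    else:
        rng = np.random.default_rng(0)
        starts = [np.concatenate([beta0, [np.log(0.02)]])]
        for _ in range(3):
            starts.append(
                np.concatenate(
                    [beta0 + rng.normal(0, 0.1, size=k), [np.log(0.02) + rng.normal(0, 1)]]
                )
            )
        best = None
        for s in starts:
            res = optimize.minimize(nll, s, method="BFGS",
                                    options={"gtol": 1e-7, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        # binomial-limit candidate: the interior parameterization can
        # stall just short of the phi -> 0 boundary
        bres = optimize_beta(_LOG_PHI_FLOOR, beta0)
        if bres.fun <= best.fun:
            theta = np.concatenate([bres.x, [_LOG_PHI_FLOOR]])
            best_fun = bres.fun
            converged = bool(bres.success or np.max(np.abs(bres.jac)) < 1e-4)
        else:
            theta = best.x
            best_fun = best.fun
            converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-3)
        phi_free = True
    if not converged:
        flags.append("non-convergence")

    at_boundary = theta[-1] <= _LOG_PHI_FLOOR
    if at_boundary or not phi_free:
        # information over beta only: the likelihood is flat in log phi
        # at the boundary (and phi is not estimated when fixed)
        nll_beta = lambda b: -_bb_loglik(np.concatenate([b, [theta[-1]]]), X, y, m)
        hess = numdiff.approx_hess(theta[:k], nll_beta)
    else:
        hess = numdiff.approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(hess.shape[0], np.nan)
        flags.append("singular-information")
    est = theta[:k]
    se = se_all[:k]
    df = k + (1 if phi_free else 0)
    resid_df = len(y) - df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df=max(resid_df, 1))
    return BetaBinomFit(
        names=list(model.names),
        estimates=est,
        std_errors=se,
        t_values=t,
        p_values=p,
        phi=0.0 if theta[-1] <= _LOG_PHI_FLOOR else float(np.exp(theta[-1])),
        log_likelihood=float(-best_fun),
        df=df,
        resid_df=resid_df,
        converged=converged,
        flags=flags,
    )


def fit_trait_regression(
    samples: pd.DataFrame,
    covariates: list[str],
    count_col: str = "n_producers",
    total_col: str = "n_genomes",
) -> BetaBinomFit:
    """Fit trait counts against sample covariates (intercept added).

    String covariates are dummy-coded against their first sorted level
    (coefficient named ``<col>[<level>]``).
    """
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        v = samples[cov]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append((v == lev).astype(float).values)
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(v.values.astype(float))
            names.append(cov)
    model = BetaBinomModel(
        X=np.column_stack(cols),
        y=samples[count_col].values,
        m=samples[total_col].values,
        names=names,
    )
    return fit_betabinom(model)


def basin_contrast(fit: BetaBinomFit, contrast: str) -> dict:
    """Wald test for one named coefficient."""
    return fit.coef(contrast)
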