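"""Per-epilocus logistic association with environmental variables.

Each polymorphic epilocus is regressed on one standardized environmental
variable at a time (constant + slope).  Model selection uses the
conjunction of the Wald test on the slope and the likelihood-ratio G test
against the constant-only model; a locus x variable pair is a candidate
only when both pass the multiplicity-corrected threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticAssociation",
    "CandidateScreen",
    "fit_null",
    "fit_logistic",
    "model_selection",
    "pseudo_r2",
    "screen_all",
    "standardize",
]

#: absolute slope (on standardized x) beyond which the fit is treated as
#: separated and excluded from candidacy
_SEPARATION_BETA = 15.0


@dataclass
class LogisticAssociation:
    """A fitted locus x variable univariate logistic model."""

    locus: str
    variable: str
    beta0: float
    beta1: float
    se_beta1: float
    loglik_full: float
    loglik_null: float
    wald: float
    g: float
    p_wald: float
    p_g: float
    pseudo_r2: float
    n: int
    converged: bool = True
    separated: bool = False
    monomorphic: bool = False
    significant: bool = False


@dataclass
class CandidateScreen:
    """Summary of a whole-matrix association screen."""

    alpha: float
    correction: str
    n_tests: int
    results: pd.DataFrame
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def standardize(x) -> np.ndarray:
    """Z-score a covariate (population sd), so slopes are scale-free."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def fit_null(y) -> tuple[float, float]:
    """Constant-only logistic fit: returns ``(loglik_null, beta0)``.

    Closed form: ``beta0 = logit(mean(y))`` and
    ``loglik = n [p ln p + (1-p) ln(1-p)]``.
    """
    y = np.asarray(y, dtype=float)
    p = y.mean()
    if p in (0.0, 1.0):
        raise ValueError("constant response: null model degenerate")
    beta0 = float(np.log(p / (1 - p)))
    ll = float(y.size * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    return ll, beta0


def _loglik(y, eta) -> float:
    # numerically safe Bernoulli log-likelihood with logit link
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y,
    x,
    locus: str = "locus",
    variable: str = "variable",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticAssociation:
    """Maximum-likelihood univariate logistic fit via IRLS (Newton).

    ``x`` is expected standardized.  Separation (diverging slope) and
    non-convergence are flagged; flagged fits are never candidates.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must align")
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("response must be binary")
    if y.min() == y.max():
        ll0 = np.nan
        return LogisticAssociation(
            locus=locus, variable=variable, beta0=np.nan, beta1=np.nan,
            se_beta1=np.nan, loglik_full=np.nan, loglik_null=np.nan,
            wald=np.nan, g=np.nan, p_wald=np.nan, p_g=np.nan,
            pseudo_r2=np.nan, n=n, monomorphic=True,
        )

    ll0, beta0_null = fit_null(y)
    design = np.column_stack([np.ones(n), x])
    beta = np.array([beta0_null, 0.0])
    ll_old = ll0
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = expit(eta)
        wdiag = mu * (1 - mu)
        score = design.T @ (y - mu)
        info = (design * wdiag[:, None]).T @ design
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        ll_new = _loglik(y, design @ beta)
        if abs(beta[1]) > _SEPARATION_BETA:
            separated = True
            break
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    eta = design @ beta
    mu = expit(eta)
    wdiag = np.clip(mu * (1 - mu), 1e-12, None)
    info = (design * wdiag[:, None]).T @ design
    try:
        cov = np.linalg.inv(info)
        se1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se1 = np.nan
    ll_full = _loglik(y, eta)
    g = max(2.0 * (ll_full - ll0), 0.0)
    wald = (beta[1] / se1) ** 2 if se1 and np.isfinite(se1) and se1 > 0 else np.nan
    p_wald = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else np.nan
    p_g = float(stats.chi2.sf(g, df=1))

    assoc = LogisticAssociation(
        locus=locus, variable=variable,
        beta0=float(beta[0]), beta1=float(beta[1]), se_beta1=se1,
        loglik_full=ll_full, loglik_null=ll0,
        wald=float(wald) if np.isfinite(wald) else np.nan,
        g=float(g), p_wald=p_wald, p_g=p_g,
        pseudo_r2=np.nan, n=n,
        converged=converged, separated=separated,
    )
    assoc.pseudo_r2 = pseudo_r2(assoc)
    return assoc


def pseudo_r2(assoc: LogisticAssociation, kind: str = "nagelkerke") -> float:
    """Pseudo-R2 of a fitted association (Nagelkerke default; McFadden
    available)."""
    ll1, ll0, n = assoc.loglik_full, assoc.loglik_null, assoc.n
    if not np.isfinite(ll1) or not np.isfinite(ll0):
        return np.nan
    if kind == "mcfadden":
        return float(1.0 - ll1 / ll0) if ll0 != 0 else np.nan
    if kind == "nagelkerke":
        cox = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
        denom = 1.0 - np.exp(2.0 * ll0 / n)
        return float(np.clip(cox / denom, 0.0, 1.0)) if denom > 0 else np.nan
    raise ValueError("kind must be 'nagelkerke' or 'mcfadden'")


def model_selection(
    assoc: LogisticAssociation,
    alpha: float,
    n_tests: int,
    correction: str = "bonferroni",
) -> bool:
    """Candidate iff BOTH Wald and G pass the corrected threshold.

    Bonferroni by default (``alpha / n_tests``); ``correction='none'``
    uses the raw alpha.  Benjamini-Hochberg is applied at the screen
    level, not per-association.  Flagged fits never qualify.
    """
    if assoc.monomorphic or assoc.separated or not assoc.converged:
        assoc.significant = False
        return False
    if correction == "bonferroni":
        thr = alpha / max(n_tests, 1)
    elif correction == "none":
        thr = alpha
    else:
        raise ValueError(
            "per-association correction must be 'bonferroni' or 'none'"
        )
    ok = (
        np.isfinite(assoc.p_wald)
        and np.isfinite(assoc.p_g)
        and assoc.p_wald < thr
        and assoc.p_g < thr
    )
    assoc.significant = bool(ok)
    return assoc.significant


def screen_all(
    binary,
    metadata: pd.DataFrame,
    variables,
    types=None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    r2_kind: str = "nagelkerke",
) -> CandidateScreen:
    """Fit every polymorphic epilocus against every variable and select.

    ``binary`` is the scorable epilocus matrix (samples x epiloci);
    ``variables`` names numeric metadata columns, standardized before
    fitting.  Returns the per-test table plus candidate counts broken
    down by panel and variable.
    """
    from .scoring import PANEL_NAMES, panel_types

    x = np.asarray(binary, dtype=float)
    if isinstance(binary, pd.DataFrame):
        locus_ids = list(binary.columns)
    else:
        locus_ids = [str(i) for i in range(x.shape[1])]
    if types is None:
        try:
            types = panel_types(locus_ids)
        except ValueError:
            types = np.asarray(["?"] * len(locus_ids))
    types = np.asarray(types)

    z = {}
    for var in variables:
        col = metadata[var].to_numpy(dtype=float)
        if col.std(ddof=0) == 0:
            warnings.warn(f"variable {var!r} is constant; skipped", UserWarning)
            continue
        z[var] = standardize(col)

    poly = np.flatnonzero((x.mean(axis=0) > 0) & (x.mean(axis=0) < 1))
    n_tests = poly.size * len(z)
    records = []
    for j in poly:
        y = x[:, j]
        for var, zv in z.items():
            assoc = fit_logistic(y, zv, locus=str(locus_ids[j]), variable=var)
            assoc.pseudo_r2 = pseudo_r2(assoc, kind=r2_kind)
            if correction in ("bonferroni", "none"):
                model_selection(assoc, alpha, n_tests, correction)
            records.append(
                {
                    "locus": assoc.locus,
                    "panel": PANEL_NAMES.get(types[j], str(types[j])),
                    "variable": var,
                    "beta0": assoc.beta0,
                    "beta1": assoc.beta1,
                    "se_beta1": assoc.se_beta1,
                    "wald": assoc.wald,
                    "g": assoc.g,
                    "p_wald": assoc.p_wald,
                    "p_g": assoc.p_g,
                    "pseudo_r2": assoc.pseudo_r2,
                    "converged": assoc.converged,
                    "separated": assoc.separated,
                    "significant": assoc.significant,
                }
            )
    results = pd.DataFrame(records)
    if correction == "fdr_bh" and len(results):
        from statsmodels.stats.multitest import multipletests

        usable = results["converged"] & ~results["separated"]
        sig = np.zeros(len(results), dtype=bool)
        if usable.any():
            p_max = results.loc[usable, ["p_wald", "p_g"]].max(axis=1)
            sig[np.flatnonzero(usable)] = multipletests(
                p_max, alpha=alpha, method="fdr_bh"
            )[0]
        results["significant"] = sig

    if len(results):
        counts = (
            results[results["significant"]]
            .groupby(["panel", "variable"], sort=True)
            .size()
            .rename("n_candidates")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["panel", "variable", "n_candidates"])
    return CandidateScreen(
        alpha=alpha, correction=correction, n_tests=n_tests,
        results=results, counts=counts,
    )
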