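"""Forward stepwise logistic risk modelling with AIC selection.

Verified SNPs (coded additively, 0/1/2 copies of the minor allele) are
screened for single-SNP significance (likelihood-ratio p < 0.05), then
entered one at a time into a binomial logistic model: at each round the
candidate whose inclusion yields the lowest AIC joins the model, stopping
when no addition lowers the AIC.  Each accepted step records the AIC and
Nagelkerke's pseudo-R-squared

    R2 = (1 - exp(2 (ll0 - ll1) / n)) / (1 - exp(2 ll0 / n)),

the Cox-Snell ratio rescaled to a [0, 1] range, interpreted here as the
share of disease risk explained by the model.  The final model is scored by
its in-sample area under the ROC curve.

``ForwardAICLogit`` is the model object; ``fit()`` returns
``StepwiseResults`` with the per-step trace, exclusions and final AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "nagelkerke_r2",
    "auc",
    "ForwardAICLogit",
    "StepwiseResults",
    "stepwise_forward_aic",
]

#: absolute coefficient above which a fit is flagged as separated
SEPARATION_CAP = 15.0


class LogisticFit(NamedTuple):
    params: np.ndarray
    llf: float
    deviance: float
    aic: float
    separation: bool


def fit_logistic(design: np.ndarray, y: np.ndarray, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood binomial logistic fit; AIC = -2 ll + 2 k.

    Perfect or quasi-perfect separation is flagged (any |coefficient| above
    ``SEPARATION_CAP`` or a non-converged likelihood); the returned
    coefficients are then clipped at the cap for downstream scoring.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
            newton_failed = False
        except np.linalg.LinAlgError:
            # singular Hessian: separation drives the Newton step off the
            # likelihood surface; BFGS still yields a (capped) direction
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            newton_failed = True
    params = np.asarray(res.params, dtype=float)
    separation = (
        newton_failed
        or bool(np.any(np.abs(params) > SEPARATION_CAP))
        or not res.mle_retvals.get("converged", True)
    )
    if separation:
        params = np.clip(params, -SEPARATION_CAP, SEPARATION_CAP)
    return LogisticFit(
        params=params,
        llf=float(res.llf),
        deviance=float(-2.0 * res.llf),
        aic=float(res.aic),
        separation=separation,
    )


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R-squared from null/full log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    if max_r2 <= 0:
        return 0.0
    return float(min(max(cox_snell / max_r2, 0.0), 1.0))


def auc(scores, y) -> float:
    """Rank-based (Mann-Whitney) AUC; ties counted one half."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


class ForwardAICLogit:
    """Forward-AIC stepwise logistic model over candidate SNPs.

    Parameters
    ----------
    y : array of 0/1 case status.
    genotypes : (n_samples, n_candidates) additive 0/1/2 matrix; NaN or -1
        marks missing calls.  Rows incomplete across the candidate set are
        dropped (complete-case).
    candidates : names of the candidate SNPs.
    p_screen : single-SNP likelihood-ratio significance threshold below
        which a candidate is admitted to the search (default 0.05).
    """

    def __init__(
        self,
        y: np.ndarray,
        genotypes: np.ndarray,
        candidates: Sequence[str] | None = None,
        p_screen: float = 0.05,
    ):
        g = np.array(genotypes, dtype=float, copy=True)
        if g.ndim == 1:
            g = g[:, None]
        g[g == -1] = np.nan
        y = np.asarray(y, dtype=float)
        if y.size != g.shape[0]:
            raise ValueError("y length must match genotype rows")
        complete = ~np.isnan(g).any(axis=1)
        self.y = y[complete]
        self.X = g[complete]
        self.candidates = (
            list(candidates)
            if candidates is not None
            else [f"snp{j}" for j in range(self.X.shape[1])]
        )
        if len(self.candidates) != self.X.shape[1]:
            raise ValueError("candidate names must match genotype columns")
        if len(self.candidates) == 0:
            raise ValueError("at least one candidate is required")
        self.p_screen = float(p_screen)
        self.n_dropped = int(g.shape[0] - self.X.shape[0])

    def fit(self) -> "StepwiseResults":
        n = self.y.size
        null_fit = fit_logistic(np.empty((n, 0)), self.y)
        ll_null = null_fit.llf

        excluded: list[tuple[str, str]] = []
        admitted: list[int] = []
        single_aic: dict[int, float] = {}
        for j, name in enumerate(self.candidates):
            f = fit_logistic(self.X[:, j], self.y)
            lr_p = float(stats.chi2.sf(2.0 * (f.llf - ll_null), 1))
            if lr_p >= self.p_screen:
                excluded.append((name, f"single-SNP p={lr_p:.3g} >= {self.p_screen:g}"))
            else:
                admitted.append(j)
                single_aic[j] = f.aic

        steps = []
        in_model: list[int] = []
        current_aic = null_fit.aic
        current_ll = ll_null
        remaining = sorted(admitted, key=lambda j: single_aic[j])
        while remaining:
            best_j, best_fit = None, None
            for j in remaining:
                try:
                    f = fit_logistic(self.X[:, in_model + [j]], self.y)
                except np.linalg.LinAlgError:
                    continue  # collinear with the current model; no AIC gain possible
                if best_fit is None or f.aic < best_fit.aic:
                    best_j, best_fit = j, f
            if best_fit is None or best_j is None:
                break
            if best_fit.aic >= current_aic:
                break
            in_model.append(best_j)
            remaining.remove(best_j)
            r2 = nagelkerke_r2(ll_null, best_fit.llf, n)
            steps.append(
                {
                    "snp_id": self.candidates[best_j],
                    "aic": best_fit.aic,
                    "aic_change": current_aic - best_fit.aic,
                    "r2": r2,
                    "r2_change": r2 - nagelkerke_r2(ll_null, current_ll, n),
                }
            )
            current_aic, current_ll = best_fit.aic, best_fit.llf

        if in_model:
            final_fit = fit_logistic(self.X[:, in_model], self.y)
            design = sm.add_constant(self.X[:, in_model], has_constant="add")
            scores = design @ final_fit.params
            final_auc = auc(scores, self.y)
        else:
            final_fit = null_fit
            final_auc = 0.5
        trace = pd.DataFrame(
            steps, columns=["snp_id", "aic", "aic_change", "r2", "r2_change"]
        )
        return StepwiseResults(
            trace=trace,
            excluded=excluded,
            final_params=final_fit.params,
            final_snps=[self.candidates[j] for j in in_model],
            final_auc=final_auc,
            null_aic=null_fit.aic,
            n_obs=n,
            n_dropped=self.n_dropped,
            separation=final_fit.separation,
        )


@dataclass
class StepwiseResults:
    """Ordered entry trace of the forward-AIC search plus the final model."""

    trace: pd.DataFrame
    excluded: list[tuple[str, str]]
    final_params: np.ndarray
    final_snps: list[str]
    final_auc: float
    null_aic: float
    n_obs: int
    n_dropped: int
    separation: bool

    def summary(self) -> str:
        lines = [
            "Forward-AIC stepwise logistic regression",
            f"  observations: {self.n_obs} (complete-case; {self.n_dropped} dropped)",
            f"  intercept-only AIC: {self.null_aic:.2f}",
            f"  {'step':<5} {'snp':<14} {'AIC':<10} {'dAIC':<8} {'R2':<7} {'dR2':<7}",
        ]
        for i, r in self.trace.iterrows():
            lines.append(
                f"  {i + 1:<5} {r.snp_id:<14} {r.aic:<10.2f} {r.aic_change:<8.2f} "
                f"{r.r2:<7.3f} {r.r2_change:<7.3f}"
            )
        for name, reason in self.excluded:
            lines.append(f"  excluded {name}: {reason}")
        lines.append(f"  final AUC: {self.final_auc:.3f}")
        if self.separation:
            lines.append("  warning: separation detected in the final fit")
        return "\n".join(lines)


def stepwise_forward_aic(
    genotypes: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[str] | None = None,
    p_screen: float = 0.05,
) -> StepwiseResults:
    """Functional wrapper around :class:`ForwardAICLogit`."""
    return ForwardAICLogit(y, genotypes, candidates, p_screen=p_screen).fit()
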