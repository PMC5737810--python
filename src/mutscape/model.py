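"""Multivariable logistic model of per-CpG mutation probability.

The model predicts the pooled binary mutation outcome of each CpG from its
methylation fraction M and the replication timing R of its megabase window:

    log(P_mut / (1 - P_mut)) = b0 + b1*M + b2*M^2 + b3*R + b4*(M x R)

M enters as a raw fraction in [0, 1] (no centering) and R on its native
scale, so coefficients are directly interpretable on the data scale. The
quadratic term makes the log-odds a parabola in M whose extremum (the
"vertex", at a reference timing r) sits at M* = -(b1 + b4*r) / (2*b2); a
vertex inside [0, 1] means mutation probability stops increasing with
methylation partway through the methylation range, a vertex above 1 means
the association is monotone increasing over all attainable methylation.

Usage follows the statsmodels pattern::

    model = CpGMutationModel.from_table(table)           # full 5-term model
    res = model.fit()
    res.params, res.bse, res.llf, res.aic
    res.auc(), res.vertex(), res.summary()

Nested-model selection (LRT at P < 0.05 on every step, plus minimum AIC)
is provided by :func:`select_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

TERMS = ("M", "M2", "R", "MxR")  # intercept is always included

#: the nested chain used for model selection, smallest first
DEFAULT_CHAIN: tuple[tuple[str, ...], ...] = (
    (),
    ("M",),
    ("M", "M2"),
    ("M", "M2", "R"),
    ("M", "M2", "R", "MxR"),
)


def _validate_terms(terms: tuple[str, ...]) -> tuple[str, ...]:
    terms = tuple(terms)
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown model terms: {sorted(unknown)}")
    if "M2" in terms and "M" not in terms:
        raise ValueError("M2 requires M (term hierarchy)")
    if "MxR" in terms and not {"M", "R"} <= set(terms):
        raise ValueError("MxR requires M and R (term hierarchy)")
    return tuple(t for t in TERMS if t in terms)  # canonical order


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded: some term separates the outcome classes."""


class CpGMutationModel:
    """Binary logistic model of CpG mutation probability.

    Parameters
    ----------
    endog : array of 0/1 mutation outcomes, one per CpG.
    m, r : methylation fractions and replication-timing values per CpG.
    terms : subset of ``("M", "M2", "R", "MxR")`` respecting the hierarchy
        (M2 needs M; MxR needs M and R). The intercept is always included.
    """

    def __init__(self, endog, m, r=None, terms: tuple[str, ...] = TERMS):
        self.terms = _validate_terms(terms)
        y = np.asarray(endog, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if np.unique(y).size < 2:
            raise ValueError("outcome has a single class; model cannot be fitted")
        m = np.asarray(m, dtype=float)
        if ("R" in self.terms or "MxR" in self.terms) and r is None:
            raise ValueError("terms involve R but no timing values supplied")
        r = np.zeros_like(m) if r is None else np.asarray(r, dtype=float)
        if not (np.isfinite(m).all() and np.isfinite(r).all()):
            raise ValueError("non-finite covariates; drop sites with missing M or R")
        self.endog = y
        self._m, self._r = m, r
        self.exog = self._design(m, r)
        self.exog_names = ["b0"] + [
            {"M": "b1", "M2": "b2", "R": "b3", "MxR": "b4"}[t] for t in self.terms
        ]
        self._r_mean = float(r.mean())

    @classmethod
    def from_table(cls, table: pd.DataFrame, terms: tuple[str, ...] = TERMS):
        """Build from a per-CpG annotation table (columns M, R, mutated)."""
        t = table
        need_r = "R" in terms or "MxR" in terms
        if need_r:
            t = t.dropna(subset=["R"])
        return cls(
            t["mutated"].to_numpy(dtype=float),
            t["M"].to_numpy(dtype=float),
            t["R"].to_numpy(dtype=float) if need_r else None,
            terms=terms,
        )

    def _design(self, m: np.ndarray, r: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(m)]
        for t in self.terms:
            cols.append({"M": m, "M2": m * m, "R": r, "MxR": m * r}[t])
        return np.column_stack(cols)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "CpGMutationResults":
        """Maximum-likelihood fit (Newton), deterministic given the input."""
        logit = sm.Logit(self.endog, self.exog)
        try:
            res = logit.fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
        except Exception as exc:  # statsmodels raises on hard separation
            raise PerfectSeparationError(str(exc)) from exc
        # soft separation: fitted probabilities collapse to 0/1
        p = res.predict()
        if np.all((p < 1e-10) | (p > 1 - 1e-10)):
            worst = self.exog_names[int(np.argmax(np.abs(res.params)))]
            raise PerfectSeparationError(
                f"complete separation of outcome classes (term {worst})"
            )
        return CpGMutationResults(self, res)


@dataclass
class LRTStep:
    """One likelihood-ratio test between adjacent nested specifications."""

    smaller: tuple[str, ...]
    larger: tuple[str, ...]
    statistic: float
    df: int
    p_value: float


@dataclass
class SelectionResult:
    """Outcome of the nested LRT/AIC model-selection chain."""

    chain: tuple[tuple[str, ...], ...]
    fits: list["CpGMutationResults"]
    steps: list[LRTStep]
    aics: list[float]
    chosen_by_lrt: tuple[str, ...]
    chosen_by_aic: tuple[str, ...]
    agreement: bool

    @property
    def chosen(self) -> tuple[str, ...]:
        return self.chosen_by_lrt


class CpGMutationResults:
    """Fitted mutation model: coefficients, uncertainty and diagnostics.

    Coefficient names follow the equation: b0 (intercept), b1 (M), b2 (M^2),
    b3 (R), b4 (M x R); absent terms are simply not estimated.
    """

    def __init__(self, model: CpGMutationModel, sm_results):
        self.model = model
        self._res = sm_results
        names = model.exog_names
        self.params = pd.Series(sm_results.params, index=names)
        self.bse = pd.Series(sm_results.bse, index=names)
        self.llf = float(sm_results.llf)
        self.nobs = int(sm_results.nobs)
        self.df_model = len(names)
        self.aic = 2 * self.df_model - 2 * self.llf
        self.converged = bool(sm_results.mle_retvals.get("converged", True))

    def predict(self, m=None, r=None) -> np.ndarray:
        """Predicted mutation probabilities (in-sample when no data given)."""
        if m is None:
            return self._res.predict()
        m = np.asarray(m, dtype=float)
        r = np.zeros_like(m) if r is None else np.asarray(r, dtype=float)
        return self._res.predict(self.model._design(m, r))

    def auc(self) -> float:
        """In-sample area under the ROC curve.

        The probability that a randomly chosen mutated CpG receives a higher
        predicted probability than a randomly chosen unmutated one, ties
        counting one half.
        """
        y = self.model.endog
        if np.unique(y).size < 2:
            raise ValueError("AUC undefined: one outcome class absent")
        return float(roc_auc_score(y, self.predict()))

    def vertex(self, r_ref: float | None = None) -> float:
        """Methylation fraction at which the log-odds parabola is extremal.

        Evaluated at the reference timing ``r_ref`` (cohort mean timing by
        default). May legitimately fall outside [0, 1]: a vertex above 1
        means the fitted association increases over the whole methylation
        range. Requires an estimated, non-zero quadratic coefficient.
        """
        if "b2" not in self.params.index:
            raise ValueError("no quadratic term in the model: vertex undefined")
        b2 = self.params["b2"]
        if b2 == 0:
            raise ValueError("b2 == 0: log-odds linear in M, no vertex")
        if r_ref is None:
            r_ref = self.model._r_mean
        b1 = self.params.get("b1", 0.0)
        b4 = self.params.get("b4", 0.0)
        return float(-(b1 + b4 * r_ref) / (2 * b2))

    def summary(self) -> str:
        lines = [
            "CpG mutation logistic model",
            f"  n = {self.nobs}, terms = intercept + {' + '.join(self.model.terms) or '(none)'}",
            f"  log-likelihood = {self.llf:.4f}   AIC = {self.aic:.4f}",
            f"  converged = {self.converged}",
            "",
            f"  {'coef':>4} {'estimate':>12} {'std err':>10} {'z':>8}",
        ]
        for name in self.params.index:
            est, se = self.params[name], self.bse[name]
            z = est / se if se > 0 else float("nan")
            lines.append(f"  {name:>4} {est:12.6g} {se:10.4g} {z:8.2f}")
        try:
            lines += ["", f"  AUC = {self.auc():.4f}"]
        except ValueError:
            pass
        if "b2" in self.params.index and self.params["b2"] != 0:
            lines.append(f"  vertex (at mean R) = {self.vertex():.4f}")
        return "\n".join(lines)

    def equation(self) -> str:
        """The fitted model as a human-readable log-odds equation."""
        sym = {"b0": "", "b1": "*M", "b2": "*M^2", "b3": "*R", "b4": "*(MxR)"}
        terms = [f"{self.params[n]:+.4g}{sym[n]}" for n in self.params.index]
        return "log(Pmut/(1-Pmut)) = " + " ".join(terms)


def lr_test(smaller: CpGMutationResults, larger: CpGMutationResults) -> LRTStep:
    """Likelihood-ratio test between two nested fits on the same data."""
    if not set(smaller.model.terms) <= set(larger.model.terms):
        raise ValueError("models are not nested")
    if smaller.nobs != larger.nobs:
        raise ValueError("fits use different numbers of observations")
    statistic = 2.0 * (larger.llf - smaller.llf)
    df = larger.df_model - smaller.df_model
    if df == 0:
        p = 1.0
        statistic = max(statistic, 0.0)
    else:
        p = float(stats.chi2.sf(statistic, df))
    return LRTStep(smaller.model.terms, larger.model.terms, float(statistic), df, p)


def select_model(
    table: pd.DataFrame,
    chain: tuple[tuple[str, ...], ...] = DEFAULT_CHAIN,
    alpha: float = 0.05,
) -> SelectionResult:
    """Walk a nested chain of specifications with LRT and AIC criteria.

    A model is selected by the LRT rule if every step from the null up to it
    improves significantly (P < ``alpha``); the largest such model wins. AIC
    independently selects the smallest-AIC model; any disagreement between
    the two criteria is reported in the result.
    """
    specs = [_validate_terms(s) for s in chain]
    for a, b in zip(specs, specs[1:]):
        if not set(a) <= set(b):
            raise ValueError(f"chain not nested: {a} -> {b}")
    fits = [CpGMutationModel.from_table(table, terms=s).fit() for s in specs]
    steps = [lr_test(s, l) for s, l in zip(fits, fits[1:])]
    aics = [f.aic for f in fits]

    chosen_idx = 0
    for i, step in enumerate(steps):
        if step.df > 0 and step.p_value < alpha:
            chosen_idx = i + 1
        else:
            break
    chosen_by_lrt = specs[chosen_idx]
    chosen_by_aic = specs[int(np.argmin(aics))]
    return SelectionResult(
        chain=tuple(specs),
        fits=fits,
        steps=steps,
        aics=aics,
        chosen_by_lrt=chosen_by_lrt,
        chosen_by_aic=chosen_by_aic,
        agreement=chosen_by_lrt == chosen_by_aic,
    )


def auc_delta(selection: SelectionResult, added_term: str = "R") -> float:
    """Percentage-point AUC improvement when ``added_term`` enters the chain.

    E.g. with the default chain, ``auc_delta(sel, "R")`` is 100 x
    (AUC of the M+M2+R model - AUC of the M+M2 model) — the paper-style
    "improvement to the AUC from incorporating replication timing".
    """
    idx = next(
        (i for i, s in enumerate(selection.chain) if added_term in s), None
    )
    if idx is None or idx == 0:
        raise ValueError(f"term {added_term!r} never enters the chain")
    return 100.0 * (selection.fits[idx].auc() - selection.fits[idx - 1].auc())


def per_sample_vertices(
    table: pd.DataFrame,
    hits: pd.DataFrame,
    terms: tuple[str, ...] = TERMS,
    r_ref: float | None = None,
) -> pd.DataFrame:
    """Refit the model on each sample's own outcome vector; one vertex per sample.

    Samples whose outcome vector has a single class, or whose fit lacks a
    usable quadratic term, are skipped. Compare groups of vertices with an
    unpaired t-test (:func:`scipy.stats.ttest_ind`).
    """
    key = pd.MultiIndex.from_frame(table[["chrom", "pos"]])
    rows = []
    for s in sorted(hits["sample"].unique()):
        sub = hits[hits["sample"] == s]
        ev = sub.set_index(["chrom", "pos"])["count"].reindex(key, fill_value=0).to_numpy()
        t = table.assign(mutated=ev >= 1)
        try:
            res = CpGMutationModel.from_table(t, terms=terms).fit()
            rows.append((s, res.vertex(r_ref=r_ref), int((ev >= 1).sum())))
        except (ValueError, PerfectSeparationError):
            continue
    return pd.DataFrame(rows, columns=["sample", "vertex", "n_mutated"])
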