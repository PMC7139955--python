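"""Cox proportional-hazards regression and Kaplan-Meier estimation.

The Cox model relates a sample's hazard to its covariates through
``h(t) = h0(t) * exp(x' beta)``.  ``fit_cox`` maximizes the partial
likelihood with either the Breslow or the Efron correction for tied
event times, using damped Newton iterations on the analytic gradient
and Hessian.  Standard errors come from the inverse observed
information; inference is Wald throughout (z tests per term, joint
chi-square tests per categorical block, HR confidence limits
``exp(beta +/- 1.96 SE)``).

``build_model`` implements the covariate-inclusion convention used for
the immune-signature models: the signature score enters together with
age, stage and primary surgical cytoreduction; when the cytoreduction
block's joint Wald p-value exceeds 0.10 the model is refit without it,
and both fits are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: threshold of the cytoreduction-retention rule
CYTOREDUCTION_DROP_P = 0.10

#: reference levels for the standard categorical covariates
DEFAULT_REFERENCES = {
    "stage": "<=2",  # lowest stage is the reference
    "cytoreduction": "Suboptimal",
    "pr_status": "negative",
    "brca_status": "wild-type",
    "col2a1_group": "Low",
}


@dataclass
class TermResult:
    """Inference for one design-matrix column."""

    name: str
    beta: float
    se: float
    z: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    block: str  # covariate the column belongs to


@dataclass
class BlockTest:
    """Joint Wald test over the indicator columns of one categorical
    covariate."""

    name: str
    chi2: float
    df: int
    p: float


@dataclass
class CoxModelResult:
    terms: dict[str, TermResult]
    blocks: dict[str, BlockTest]
    log_likelihood: float
    n: int
    n_events: int
    ties: str
    covariance: np.ndarray | None = None
    design_columns: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        return self.terms[name]

    def block_p(self, name: str) -> float:
        """p-value for a covariate: the joint block test if categorical,
        the per-term Wald p otherwise."""
        if name in self.blocks:
            return self.blocks[name].p
        return self.terms[name].p

    def to_dict(self) -> dict:
        return {
            "terms": {
                k: {
                    "beta": t.beta,
                    "se": t.se,
                    "z": t.z,
                    "p": t.p,
                    "hr": t.hr,
                    "ci": [t.ci_low, t.ci_high],
                    "block": t.block,
                }
                for k, t in self.terms.items()
            },
            "blocks": {
                k: {"chi2": b.chi2, "df": b.df, "p": b.p}
                for k, b in self.blocks.items()
            },
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "notes": self.notes,
        }


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    references: dict[str, str | None] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand covariates to a numeric design matrix.

    Object/categorical columns are reference-coded: one indicator per
    non-reference level, named ``term[level]``.  Returns the design and
    a mapping covariate -> its design columns.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    cols: dict[str, pd.Series] = {}
    blocks: dict[str, list[str]] = {}
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"covariate {term!r} absent from the table")
        col = data[term]
        if col.isna().any():
            raise ValueError(f"covariate {term!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.astype(str).unique()))
            ref = refs.get(term)
            if ref is None or ref not in levels:
                ref = levels[0]
            blocks[term] = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                cols[name] = (col.astype(str) == lev).astype(float)
                blocks[term].append(name)
        else:
            cols[term] = col.astype(float)
            blocks[term] = [term]
    design = pd.DataFrame(cols, index=data.index)
    for name in design.columns:
        if design[name].nunique() < 2:
            raise ValueError(f"design column {name!r} is constant")
    return design, blocks


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _group_by_event_time(
    t: np.ndarray, e: np.ndarray
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Per distinct event time: (time, indices of events at that time,
    indices of the risk set)."""
    order = np.argsort(t, kind="stable")
    out = []
    for tt in np.unique(t[e == 1]):
        events = np.where((t == tt) & (e == 1))[0]
        risk = np.where(t >= tt)[0]
        out.append((float(tt), events, risk))
    return out


def cox_loglik(
    beta: np.ndarray, X: np.ndarray, t: np.ndarray, e: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood with analytic gradient and Hessian.

    Breslow treats tied events as sharing the full risk-set denominator;
    Efron removes the tied events' own contribution in fractions.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow: partial likelihood is invariant to a common
    # shift in eta only through the risk-set structure, so shift globally
    shift = eta.max()
    w = np.exp(eta - shift)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for _, events, risk in _group_by_event_time(t, e):
        d = len(events)
        xs = X[events].sum(axis=0)
        s0 = w[risk].sum()
        s1 = (w[risk, None] * X[risk]).sum(axis=0)
        s2 = (w[risk, None, None] * X[risk, :, None] * X[risk, None, :]).sum(axis=0)
        if ties == "breslow" or d == 1:
            ll += eta[events].sum() - d * (np.log(s0) + shift)
            mu = s1 / s0
            grad += xs - d * mu
            hess -= d * (s2 / s0 - np.outer(mu, mu))
        elif ties == "efron":
            t0 = w[events].sum()
            t1 = (w[events, None] * X[events]).sum(axis=0)
            t2 = (w[events, None, None] * X[events, :, None] * X[events, None, :]).sum(
                axis=0
            )
            ll += eta[events].sum()
            for l in range(d):
                f = l / d
                a0 = s0 - f * t0
                a1 = s1 - f * t1
                a2 = s2 - f * t2
                ll -= np.log(a0) + shift
                mu = a1 / a0
                grad_term = mu
                grad -= grad_term
                hess -= a2 / a0 - np.outer(mu, mu)
            grad += xs
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return float(ll), grad, hess


def _newton_fit(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    ties: str,
    max_iter: int = 100,
    score_tol: float = 1e-9,
    ll_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Damped Newton maximization; returns (beta, covariance, loglik)."""
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = cox_loglik(beta, X, t, e, ties)
    for it in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix: {err}") from err
        # step halving keeps the likelihood non-decreasing
        alpha = 1.0
        for _ in range(40):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = cox_loglik(cand, X, t, e, ties)
            if ll_new >= ll - 1e-13:
                break
            alpha /= 2.0
        else:
            raise RuntimeError("step halving failed to improve the likelihood")
        delta_ll = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 15:
            # log-HR beyond +-15 is never a finite MLE in practice
            raise RuntimeError(
                "diverging coefficients (|beta| > 15): monotone likelihood / "
                "complete separation; consider penalization (not provided)"
            )
        if np.abs(grad).max() < score_tol or abs(delta_ll) < ll_tol:
            cov = np.linalg.inv(-hess)
            return beta, cov, ll
    raise RuntimeError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(max |score| = {np.abs(grad).max():.3g})"
    )


def fit_cox(
    data: pd.DataFrame,
    terms: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
    references: dict[str, str | None] | None = None,
) -> CoxModelResult:
    """Fit a Cox PH model by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    data
        Table with one row per sample: duration, event indicator and
        covariates.  Categorical covariates are expanded to
        reference-coded indicators.
    terms
        Covariate column names to include.
    ties
        ``"breslow"`` (default, matching SAS PROC PHREG's default) or
        ``"efron"``.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    t = data[duration_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=float)
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("event column must be 0/1")
    if (t <= 0).any():
        raise ValueError("durations must be positive")
    if e.sum() < 1:
        raise ValueError("no events in the data")
    design, blocks = build_design(data, terms, references)
    X = design.to_numpy(dtype=float)
    # center columns for numerical stability; beta is shift-invariant
    X = X - X.mean(axis=0)
    beta, cov, ll = _newton_fit(X, t, e, ties)
    se = np.sqrt(np.diag(cov))
    term_results: dict[str, TermResult] = {}
    col_index = {c: i for i, c in enumerate(design.columns)}
    for block, colnames in blocks.items():
        for c in colnames:
            i = col_index[c]
            z = beta[i] / se[i]
            p = 2.0 * stats.norm.sf(abs(z))
            term_results[c] = TermResult(
                name=c,
                beta=float(beta[i]),
                se=float(se[i]),
                z=float(z),
                p=float(max(p, np.finfo(float).tiny)),
                hr=float(np.exp(beta[i])),
                ci_low=float(np.exp(beta[i] - 1.959963984540054 * se[i])),
                ci_high=float(np.exp(beta[i] + 1.959963984540054 * se[i])),
                block=block,
            )
    block_tests: dict[str, BlockTest] = {}
    for block, colnames in blocks.items():
        if len(colnames) < 2:
            continue
        idx = [col_index[c] for c in colnames]
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        p = float(stats.chi2.sf(chi2, df=len(idx)))
        block_tests[block] = BlockTest(block, chi2, len(idx), max(p, np.finfo(float).tiny))
    return CoxModelResult(
        terms=term_results,
        blocks=block_tests,
        log_likelihood=ll,
        n=len(t),
        n_events=int(e.sum()),
        ties=ties,
        covariance=cov,
        design_columns=list(design.columns),
    )


# ---------------------------------------------------------------------------
# signature model construction


@dataclass
class SignatureModel:
    """A fitted signature model together with the covariate-inclusion
    decision trail."""

    signature: str
    final: CoxModelResult
    full: CoxModelResult
    cytoreduction_dropped: bool
    cytoreduction_p: float | None


def build_model(
    data: pd.DataFrame,
    signature: str,
    base_covariates: tuple[str, ...] = ("age", "stage", "cytoreduction"),
    extra_covariates: tuple[str, ...] = (),
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
    drop_p: float = CYTOREDUCTION_DROP_P,
) -> SignatureModel:
    """Multivariable model for one standardized signature score.

    Fits signature + base covariates (+ extras); if cytoreduction is
    among the covariates and its joint Wald p exceeds ``drop_p``, the
    model is refit without it.  Both fits and the decision are kept.
    """
    zcol = f"Z_{signature}" if f"Z_{signature}" in data.columns else signature
    if zcol not in data.columns:
        raise KeyError(f"signature score {signature!r} not found in the table")
    terms = [zcol] + [c for c in base_covariates if c != zcol] + list(extra_covariates)
    full = fit_cox(data, terms, duration_col, event_col, ties)
    cyto_p: float | None = None
    dropped = False
    final = full
    if "cytoreduction" in terms:
        cyto_p = full.block_p("cytoreduction")
        if cyto_p > drop_p:
            dropped = True
            reduced_terms = [c for c in terms if c != "cytoreduction"]
            final = fit_cox(data, reduced_terms, duration_col, event_col, ties)
            final.notes.append(
                f"cytoreduction not included (joint Wald p = {cyto_p:.3g} > {drop_p})"
            )
            logger.info(
                "build_model[%s]: cytoreduction dropped (p = %.3g > %.2f)",
                signature,
                cyto_p,
                drop_p,
            )
    return SignatureModel(
        signature=signature,
        final=final,
        full=full,
        cytoreduction_dropped=dropped,
        cytoreduction_p=cyto_p,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


def kaplan_meier_curve(
    t: np.ndarray, e: np.ndarray, group: str = ""
) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    if len(t) == 0:
        raise ValueError(f"empty group {group!r}")
    times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for tt in times:
        n_i = int((t >= tt).sum())
        d_i = int(((t == tt) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KMCurve(
        group=group,
        times=times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        censor_times=np.sort(t[e == 0]),
    )


def kaplan_meier(
    data: pd.DataFrame,
    groups: pd.Series,
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> tuple[dict[str, KMCurve], CoxModelResult]:
    """Per-group product-limit curves plus the two-group hazard ratio
    from a univariable Cox fit on the group indicator (High vs Low)."""
    curves: dict[str, KMCurve] = {}
    for g in sorted(groups.unique()):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        curves[str(g)] = kaplan_meier_curve(
            data.loc[sel, duration_col].to_numpy(),
            data.loc[sel, event_col].to_numpy(),
            group=str(g),
        )
    tab = data[[duration_col, event_col]].copy()
    tab["group"] = groups.astype(str)
    fit = fit_cox(
        tab,
        ["group"],
        duration_col,
        event_col,
        ties=ties,
        references={"group": "Low"},
    )
    return curves, fit


def plot_km(curves: dict[str, KMCurve], path: str, title: str = "") -> None:
    """Step-plot the curves to a file (solid High, dotted Low, X at
    censoring times)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    styles = {"High": "-", "Low": ":"}
    for name, c in curves.items():
        xs = np.concatenate([[0.0], np.repeat(c.times, 2)])
        ys = np.concatenate([[1.0, 1.0], np.repeat(c.survival, 2)[:-1]])
        ax.plot(xs, ys, styles.get(name, "-"), label=name)
        cy = [c.survival_at(ct) for ct in c.censor_times]
        ax.plot(c.censor_times, cy, "x", ms=5, color=ax.lines[-1].get_color())
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
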