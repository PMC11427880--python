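"""Determinants of question quality: multinomial logistic regression
of the quality tier on content and language variables, plus two-group
descriptive tests (platform contrasts).

The regression is a maximum-likelihood softmax model fitted by Newton
iterations with step-halving, expressed as log-odds contrasts of each
tier against a reference tier (high quality by default, since that is
what every question aspires to). Standard errors come from the inverse
observed information. Quasi-complete separation — a predictor that
perfectly splits tiers, sending its coefficient toward infinity while
the gradient vanishes — is detected and flagged rather than hidden; an
optional ridge penalty stabilises such fits and its strength is
recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QualityDeterminantsModel",
    "DeterminantsResults",
    "fit_multinomial",
    "group_tests",
]

logger = logging.getLogger(__name__)

SEPARATION_COEF = 10.0  # |log-odds| beyond this is flagged as separation


@dataclass
class DeterminantsResults:
    """Fitted multinomial-logit results.

    ``params`` is a tidy frame with one row per (contrast, term):
    estimate, se, z, p, separation flag. ``contrasts`` are
    "<level> vs <reference>" strings in level order.
    """

    params: pd.DataFrame
    llf: float
    llnull: float
    n_obs: int
    levels: tuple
    reference: object
    converged: bool
    n_iter: int
    ridge: float
    separation_terms: tuple[str, ...]
    coef_: np.ndarray = field(repr=False)  # (p, K-1) internal layout
    cov_: np.ndarray = field(repr=False)
    exog_names: tuple[str, ...] = ()

    @property
    def contrasts(self) -> list[str]:
        return [f"{lv} vs {self.reference}" for lv in self.levels if lv != self.reference]

    def predict(self, exog: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Per-observation probabilities over the outcome levels."""
        X = _with_intercept(np.asarray(exog, dtype=float))
        P = _softmax_probs(X, self.coef_)
        cols = [self.reference] + [lv for lv in self.levels if lv != self.reference]
        order = [cols.index(lv) for lv in self.levels]
        return P[:, order]

    def pseudo_r2(self) -> float:
        """McFadden pseudo R-squared."""
        return 1.0 - self.llf / self.llnull if self.llnull != 0 else np.nan

    def summary(self) -> str:
        lines = [
            "Multinomial logistic regression of question quality",
            f"  n = {self.n_obs}, levels = {list(self.levels)}, "
            f"reference = {self.reference!r}",
            f"  log-likelihood = {self.llf:.4f}  (null {self.llnull:.4f}, "
            f"McFadden R2 = {self.pseudo_r2():.4f})",
            f"  converged = {self.converged} in {self.n_iter} iterations"
            + (f", ridge = {self.ridge}" if self.ridge else ""),
        ]
        if self.separation_terms:
            lines.append(
                "  WARNING quasi-complete separation suspected for: "
                + ", ".join(self.separation_terms)
            )
        for contrast, block in self.params.groupby("contrast", sort=False):
            lines.append(f"\n  {contrast}")
            lines.append(f"    {'term':<24}{'coef':>10}{'se':>10}{'z':>9}{'p':>9}")
            for row in block.itertuples(index=False):
                flag = " *sep*" if row.separation else ""
                lines.append(
                    f"    {row.term:<24}{row.estimate:>10.3f}{row.se:>10.3f}"
                    f"{row.z:>9.2f}{row.p:>9.3g}{flag}"
                )
        return "\n".join(lines)


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _softmax_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Probabilities with the reference level in column 0.

    ``B`` is (p, K-1): coefficients for the non-reference levels.
    """
    eta = np.column_stack([np.zeros(len(X)), X @ B])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def _loglik(X, Ymat, B, ridge):
    P = _softmax_probs(X, B)
    ll = float(np.sum(Ymat * np.log(np.clip(P, 1e-300, None))))
    if ridge:
        ll -= 0.5 * ridge * float((B[1:] ** 2).sum())  # intercepts unpenalised
    return ll


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    deficient = s < tol
    if deficient.any():
        involved = set()
        for row in vt[deficient]:
            involved.update(np.array(names)[np.abs(row) > 1e-6].tolist())
        raise ValueError(
            "design matrix is rank deficient; collinear columns involve: "
            + ", ".join(sorted(involved))
        )


def fit_multinomial(
    outcome,
    predictors: pd.DataFrame | np.ndarray | None = None,
    reference=None,
    ridge: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> DeterminantsResults:
    """ML softmax regression of ``outcome`` on ``predictors``.

    ``outcome`` holds the quality levels (any hashable codes, 1/2/3 in
    the reference pipeline); ``reference`` defaults to the smallest
    level (high quality = 1). ``predictors=None`` fits the
    intercept-only model. ``ridge`` adds an L2 penalty on the
    non-intercept coefficients, for separable data.
    """
    y = pd.Series(list(outcome))
    levels = tuple(sorted(y.unique()))
    if len(levels) < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed")

    if predictors is None:
        Xraw = np.empty((len(y), 0))
        names: list[str] = []
    elif isinstance(predictors, pd.DataFrame):
        Xraw = predictors.to_numpy(dtype=float)
        names = [str(c) for c in predictors.columns]
    else:
        Xraw = np.asarray(predictors, dtype=float)
        names = [f"x{i + 1}" for i in range(Xraw.shape[1])]
    if not np.isfinite(Xraw).all():
        raise ValueError("predictors contain non-finite values")
    X = _with_intercept(Xraw)
    exog_names = ["intercept"] + names
    n, p = X.shape
    others = [lv for lv in levels if lv != reference]
    K1 = len(others)
    if n <= p * K1:
        logger.warning("few observations (%d) for %d parameters", n, p * K1)
    _check_rank(X, exog_names)

    # one-hot with reference first
    Ymat = np.zeros((n, K1 + 1))
    Ymat[np.arange(n), 0] = (y == reference).to_numpy()
    for j, lv in enumerate(others, start=1):
        Ymat[np.arange(n), j] = (y == lv).to_numpy()

    B = np.zeros((p, K1))
    ll = _loglik(X, Ymat, B, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _softmax_probs(X, B)
        grad = np.empty((p, K1))
        for j in range(K1):
            grad[:, j] = X.T @ (Ymat[:, j + 1] - P[:, j + 1])
        if ridge:
            grad[1:] -= ridge * B[1:]
        g = grad.reshape(-1, order="F")

        H = np.zeros((p * K1, p * K1))
        for j in range(K1):
            for l in range(j, K1):
                w = P[:, j + 1] * ((1.0 if j == l else 0.0) - P[:, l + 1])
                blk = X.T @ (X * w[:, None])
                H[j * p:(j + 1) * p, l * p:(l + 1) * p] = blk
                if l != j:
                    H[l * p:(l + 1) * p, j * p:(j + 1) * p] = blk
        if ridge:
            pen = np.ones(p) * ridge
            pen[0] = 0.0
            H += np.diag(np.tile(pen, K1))

        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p * K1), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]

        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            Bnew = B + scale * step.reshape((p, K1), order="F")
            llnew = _loglik(X, Ymat, Bnew, ridge)
            if llnew >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            break  # no ascent step found: stationary (or separable) point
        dll = llnew - ll
        B, ll = Bnew, llnew
        if np.max(np.abs(g)) < tol * max(1.0, n) or dll < tol:
            converged = True
            break

    # diagnostics ---------------------------------------------------------
    grad_norm = float(np.max(np.abs(g)))
    sep_mask = np.abs(B) > SEPARATION_COEF
    separation_terms = tuple(
        exog_names[i] for i in range(p) if sep_mask[i].any()
    )
    if separation_terms:
        logger.warning(
            "quasi-complete separation suspected (|coef| > %.0f, max|grad| %.2e): %s%s",
            SEPARATION_COEF, grad_norm, ", ".join(separation_terms),
            f"; ridge={ridge} applied" if ridge else "",
        )
    if not converged and not separation_terms:
        raise RuntimeError(
            f"multinomial fit did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll:.6f}, max|grad| {grad_norm:.3e})"
        )

    # observed information at the optimum (penalised if ridge > 0)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; using pseudo-inverse")
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape((p, K1), order="F")

    counts = Ymat.sum(axis=0)
    pk = counts / counts.sum()
    llnull = float(np.sum(counts * np.log(np.clip(pk, 1e-300, None))))

    rows = []
    for j, lv in enumerate(others):
        contrast = f"{lv} vs {reference}"
        for i, term in enumerate(exog_names):
            est, s = float(B[i, j]), float(se[i, j])
            z = est / s if s > 0 else np.inf * np.sign(est)
            pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
            rows.append(
                {
                    "contrast": contrast,
                    "term": term,
                    "estimate": est,
                    "se": s,
                    "z": z,
                    "p": pval,
                    "separation": bool(sep_mask[i, j]),
                }
            )
    params = pd.DataFrame(rows)
    return DeterminantsResults(
        params=params,
        llf=_loglik(X, Ymat, B, 0.0),
        llnull=llnull,
        n_obs=n,
        levels=levels,
        reference=reference,
        converged=converged,
        n_iter=it,
        ridge=ridge,
        separation_terms=separation_terms,
        coef_=B,
        cov_=cov,
        exog_names=tuple(exog_names),
    )


class QualityDeterminantsModel:
    """Model object tying quality tiers to content/language predictors.

    statsmodels-style: construct from data, then ``fit()`` returns a
    :class:`DeterminantsResults`.
    """

    def __init__(self, endog, exog: pd.DataFrame | None, reference=None):
        self.endog = pd.Series(list(endog))
        self.exog = exog
        self.reference = reference

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, quality_col: str = "quality",
        predictors: list[str] | None = None, reference=None,
    ) -> "QualityDeterminantsModel":
        cols = predictors or [c for c in data.columns if c not in (quality_col, "id")]
        return cls(data[quality_col], data[cols], reference=reference)

    def fit(self, ridge: float = 0.0, **kwargs) -> DeterminantsResults:
        return fit_multinomial(
            self.endog, self.exog, reference=self.reference, ridge=ridge, **kwargs
        )


# ---------------------------------------------------------------------------
# Two-group descriptive tests (platform contrasts)
# ---------------------------------------------------------------------------


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique().tolist())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def group_tests(
    data: pd.DataFrame,
    group_col: str = "platform",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable two-group comparison report.

    Binary variables are compared as proportions with a
    continuity-corrected Pearson chi-square on the 2x2 table; numeric
    variables as means with a Welch (unequal-variance) t test. Exactly
    two groups are required. A zero-variance numeric variable is
    reported as skipped with the reason, not silently dropped.
    """
    groups = list(pd.unique(data[group_col].dropna()))
    if len(groups) != 2:
        raise ValueError(f"group_tests needs exactly 2 groups, got {groups}")
    g1, g2 = groups
    d1 = data[data[group_col] == g1]
    d2 = data[data[group_col] == g2]
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("both groups must be nonempty")
    if variables is None:
        variables = [
            c for c in data.columns
            if c not in (group_col, "id") and pd.api.types.is_numeric_dtype(data[c])
        ]

    rows = []
    for var in variables:
        x1 = d1[var].dropna().to_numpy(dtype=float)
        x2 = d2[var].dropna().to_numpy(dtype=float)
        base = {"variable": var, "group_1": g1, "group_2": g2}
        if _is_binary(data[var]):
            table = np.array(
                [[x1.sum(), len(x1) - x1.sum()], [x2.sum(), len(x2) - x2.sum()]]
            )
            if (table.sum(axis=0) == 0).any():
                rows.append({**base, "kind": "proportion", "skipped": "degenerate 2x2 table"})
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            rows.append(
                {
                    **base, "kind": "proportion",
                    "value_1": x1.mean(), "value_2": x2.mean(),
                    "statistic": float(chi2), "p": float(p),
                    "direction": g1 if x1.mean() > x2.mean() else g2,
                    "skipped": "",
                }
            )
        else:
            if np.var(x1) == 0 and np.var(x2) == 0:
                rows.append({**base, "kind": "mean", "skipped": "zero variance in both groups"})
                continue
            t, p = stats.ttest_ind(x1, x2, equal_var=False)
            rows.append(
                {
                    **base, "kind": "mean",
                    "value_1": float(x1.mean()), "value_2": float(x2.mean()),
                    "statistic": float(t), "p": float(p),
                    "direction": g1 if x1.mean() > x2.mean() else g2,
                    "skipped": "",
                }
            )
    return pd.DataFrame(rows)
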