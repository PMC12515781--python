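"""Propensity-score matching with standardized-mean-difference balance.

Comparison cohorts are matched 1:1 without replacement to a fixed
reference cohort on sex, age and BMI: a logistic propensity model is
fit by iteratively reweighted least squares, subjects are matched by
greedy nearest neighbour on the logit of the score (reference subjects
processed in descending score order, so hard-to-match subjects are
served first), and balance is reported as the absolute standardized
mean difference (SMD) per covariate, with |SMD| < 0.1 the conventional
adequacy threshold.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

BALANCE_THRESHOLD = 0.1
DEFAULT_COVARIATES = ("age", "sex", "bmi")


class MatchingError(Exception):
    pass


class DegenerateCovariateError(MatchingError):
    """Zero pooled variance with unequal means: SMD is undefined."""


class SeparationError(MatchingError):
    """A covariate perfectly separates reference from pool."""


@dataclass
class PropensityModel:
    """Fitted logistic propensity model (reference coded 1, pool 0)."""

    coefficients: dict[str, float]
    converged: bool
    n_iterations: int
    scores: pd.Series  # propensity in (0,1), indexed by subject id

    def logit_scores(self) -> pd.Series:
        p = self.scores.clip(1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


@dataclass
class MatchResult:
    pairs: list[tuple[str, str, float]]  # (reference id, matched id, logit distance)
    unmatched_reference: list[str]
    caliper_used: float | None

    @property
    def reference_ids(self) -> list[str]:
        return [r for r, _, _ in self.pairs]

    @property
    def matched_ids(self) -> list[str]:
        return [m for _, m, _ in self.pairs]


@dataclass
class BalanceReport:
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    max_abs_smd_after: float
    balanced: bool
    threshold: float = BALANCE_THRESHOLD

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def smd(
    group_a: Sequence[float], group_b: Sequence[float], kind: str = "continuous"
) -> float:
    """Standardized mean difference between two samples.

    Continuous: (mean_a - mean_b) / sqrt((var_a + var_b) / 2) with
    sample variances; binary: the analogous proportion formula with
    Bernoulli variances.  Identical degenerate samples give 0; a zero
    pooled variance with unequal means is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        denom = math.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        diff = pa - pb
    elif kind == "continuous":
        if a.size < 2 or b.size < 2:
            raise MatchingError("continuous smd requires >= 2 observations per group")
        denom = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        diff = a.mean() - b.mean()
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    if denom == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateCovariateError(
            "zero pooled variance with unequal means; SMD undefined"
        )
    return float(diff / denom)


def _is_binary(x: np.ndarray) -> bool:
    return set(np.unique(x)).issubset({0.0, 1.0})


def _check_separation(
    X: pd.DataFrame, y: np.ndarray, covariates: Sequence[str]
) -> None:
    for c in covariates:
        ref = X.loc[y == 1, c].to_numpy()
        pool = X.loc[y == 0, c].to_numpy()
        if ref.max() < pool.min() or pool.max() < ref.min():
            raise SeparationError(f"covariate {c!r} perfectly separates the groups")


def fit_propensity(
    reference: pd.DataFrame,
    pool: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> PropensityModel:
    """Fit the logistic propensity model (reference = 1, pool = 0).

    Continuous covariates are standardized internally (z-score on the
    combined sample); binary 0/1 covariates enter raw, so their
    coefficients are log odds ratios.  Fitting uses iteratively
    reweighted least squares with the given coefficient tolerance.
    """
    if len(reference) == 0 or len(pool) == 0:
        raise MatchingError("both reference and pool must be non-empty")
    X = pd.concat([reference[list(covariates)], pool[list(covariates)]])
    y = np.concatenate([np.ones(len(reference)), np.zeros(len(pool))])
    _check_separation(X, y, covariates)

    Xs = X.astype(float).copy()
    for c in covariates:
        col = Xs[c].to_numpy()
        if not _is_binary(col):
            sd = col.std(ddof=1)
            if sd == 0:
                raise DegenerateCovariateError(f"covariate {c!r} is constant")
            Xs[c] = (col - col.mean()) / sd
    design = sm.add_constant(Xs, prepend=True, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise MatchingError(f"propensity model failed to fit: {exc}") from exc
    converged = bool(getattr(res, "converged", True))
    n_iter = len(res.fit_history.get("deviance", [])) if res.fit_history else maxiter
    if not converged:
        raise MatchingError(
            f"propensity model did not converge in {maxiter} IRLS iterations"
        )
    scores = pd.Series(res.predict(design), index=X.index, name="propensity")
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    coefs = {name: float(v) for name, v in res.params.items()}
    return PropensityModel(
        coefficients=coefs, converged=converged, n_iterations=n_iter, scores=scores
    )


def match_nearest(
    reference_scores: pd.Series,
    pool_scores: pd.Series,
    caliper: float | str | None = "auto",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity.

    Reference subjects are processed in descending score order (ties by
    subject id); each takes the closest unused pool subject, skipped if
    the logit distance exceeds the caliper.  ``caliper="auto"`` uses
    0.2 x SD of the combined logit scores, the standard width.
    """
    if len(pool_scores) == 0:
        raise MatchingError("empty matching pool")
    if len(pool_scores) < len(reference_scores):
        warnings.warn(
            "pool smaller than reference; matching will be partial", stacklevel=2
        )

    def logit(p):
        p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    ref_l = pd.Series(logit(reference_scores), index=reference_scores.index)
    pool_l = pd.Series(logit(pool_scores), index=pool_scores.index)
    if caliper == "auto":
        combined = np.concatenate([ref_l.to_numpy(), pool_l.to_numpy()])
        caliper_used = 0.2 * float(np.std(combined, ddof=1)) if len(combined) > 1 else None
    else:
        caliper_used = caliper

    order = sorted(ref_l.index, key=lambda sid: (-ref_l[sid], str(sid)))
    available = dict(pool_l.items())
    pairs: list[tuple[str, str, float]] = []
    unmatched: list[str] = []
    for rid in order:
        if not available:
            unmatched.append(rid)
            continue
        best_id, best_d = min(
            available.items(), key=lambda kv: (abs(kv[1] - ref_l[rid]), str(kv[0]))
        )
        best_d = abs(best_d - ref_l[rid])
        if caliper_used is not None and best_d > caliper_used:
            unmatched.append(rid)
            continue
        pairs.append((rid, best_id, float(best_d)))
        del available[best_id]
    return MatchResult(pairs=pairs, unmatched_reference=unmatched, caliper_used=caliper_used)


def match_refined(
    reference: pd.DataFrame,
    pool: pd.DataFrame,
    model: PropensityModel,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    caliper: float | str | None = "auto",
    exact: Sequence[str] = ("sex",),
) -> MatchResult:
    """Greedy matching within a propensity caliper, refined on covariates.

    Classic caliper matching: reference subjects are processed in
    descending propensity order; candidates are the unused pool
    subjects inside the logit-score caliper that agree exactly on the
    ``exact`` covariates (sex by default), and among them the one
    closest in Euclidean z-score distance on the remaining covariates
    is taken.  Balances each covariate individually far better than
    score distance alone; subjects with no candidate stay unmatched.
    """
    lg = model.logit_scores()
    ref_l = lg.loc[reference.index]
    pool_l = lg.loc[pool.index]
    if caliper == "auto":
        caliper_used = 0.2 * float(lg.std(ddof=1))
    else:
        caliper_used = caliper
    cont = [c for c in covariates if c not in exact]
    comb = pd.concat([reference[cont], pool[cont]]).astype(float)
    mu, sd = comb.mean(), comb.std(ddof=1).replace(0.0, 1.0)
    rz = ((reference[cont] - mu) / sd).to_numpy()
    pz = ((pool[cont] - mu) / sd).to_numpy()
    pool_ids = list(pool.index)
    available = np.ones(len(pool), dtype=bool)
    order = sorted(
        range(len(reference)),
        key=lambda i: (-ref_l.iloc[i], str(reference.index[i])),
    )
    pairs: list[tuple[str, str, float]] = []
    unmatched: list[str] = []
    for i in order:
        ok = available.copy()
        if caliper_used is not None:
            ok &= np.abs(pool_l.to_numpy() - ref_l.iloc[i]) <= caliper_used
        for c in exact:
            ok &= pool[c].to_numpy() == reference[c].iloc[i]
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            unmatched.append(str(reference.index[i]))
            continue
        d = ((pz[idx] - rz[i]) ** 2).sum(axis=1)
        j = idx[int(np.argmin(d))]
        available[j] = False
        pairs.append(
            (
                str(reference.index[i]),
                str(pool_ids[j]),
                float(abs(pool_l.iloc[j] - ref_l.iloc[i])),
            )
        )
    return MatchResult(pairs=pairs, unmatched_reference=unmatched, caliper_used=caliper_used)


def balance_report(
    reference: pd.DataFrame,
    matched: pd.DataFrame,
    pre_pool: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    binary: Sequence[str] = ("sex",),
    threshold: float = BALANCE_THRESHOLD,
) -> BalanceReport:
    """Per-covariate SMD before (reference vs raw pool) and after matching."""
    if len(matched) == 0:
        raise MatchingError("no matched subjects; cannot assess balance")
    before, after = {}, {}
    for c in covariates:
        kind = "binary" if c in binary else "continuous"
        try:
            before[c] = smd(reference[c], pre_pool[c], kind)
            after[c] = smd(reference[c], matched[c], kind)
        except MatchingError:
            # too few matched subjects to standardize this covariate
            before.setdefault(c, math.nan)
            after[c] = math.nan
    finite = [abs(v) for v in after.values() if not math.isnan(v)]
    max_after = max(finite) if finite else math.nan
    return BalanceReport(
        smd_before=before,
        smd_after=after,
        max_abs_smd_after=max_after,
        balanced=bool(finite) and max_after < threshold,
        threshold=threshold,
    )


def match_cohort(
    reference: pd.DataFrame,
    pool: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    caliper: float | str | None = "auto",
    refine: bool = True,
) -> tuple[MatchResult, BalanceReport, PropensityModel]:
    """Fit, match and assess balance in one call.

    With ``refine`` (default) the covariate-refined caliper matching of
    :func:`match_refined` is used; otherwise plain nearest-neighbour on
    the logit score.  Balance is computed on the matched samples: the
    matched reference subset versus the matched pool subset.
    """
    model = fit_propensity(reference, pool, covariates)

    def _run(cal):
        if refine:
            return match_refined(reference, pool, model, covariates, cal)
        return match_nearest(
            model.scores.loc[reference.index], model.scores.loc[pool.index], cal
        )

    result = _run(caliper)
    if not result.pairs and caliper is not None:
        warnings.warn(
            "caliper produced no pairs; falling back to uncalipered matching",
            stacklevel=2,
        )
        result = _run(None)
    if result.pairs:
        report = balance_report(
            reference.loc[result.reference_ids],
            pool.loc[result.matched_ids],
            pool,
            covariates,
        )
    else:
        raise MatchingError("matching produced no pairs (caliper too narrow?)")
    return result, report, model
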