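"""Propensity-score estimation, 1:1 caliper matching, and balance.

The exposure (age-mismatched graft) is modeled by maximum-likelihood
logistic regression on the design covariates; matching is greedy 1:1
nearest-neighbor without replacement within a caliper, with the exposed
rows processed in a seeded random order; balance is summarized by
standardized mean differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "PropensityModel",
    "MatchResult",
    "fit_propensity",
    "match_1to1",
    "standardized_mean_difference",
    "balance_table",
    "DEFAULT_PS_COVARIATES",
]

#: Matching covariates: graft type/size, donor sex, donor-recipient sex
#: mismatch, center volume, and recipient age, sex, BSA, diagnosis,
#: MELD, status 1, and pretransplant admission status.
DEFAULT_PS_COVARIATES = [
    "size_class", "donor_sex", "sex_mismatch", "center_volume_class",
    "recipient_age", "recipient_sex", "recipient_bsa", "diagnosis",
    "meld", "status1", "admission",
]

_CATEGORICAL_REFERENCE = {
    # documented reference levels for one-hot encoding
    "size_class": "normal",
    "center_volume_class": "high",
    "diagnosis": "biliary_atresia",
    "admission": "home",
    "donor_sex": "F",
    "recipient_sex": "F",
}


@dataclass
class PropensityModel:
    """Fitted logistic exposure model."""
    covariate_names: list
    coefficients: pd.Series
    intercept: float
    _design_columns: list = field(repr=False, default_factory=list)

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        """Propensity scores in (0, 1) for each cohort row."""
        x = _design_matrix(cohort, self.covariate_names)
        x = x.reindex(columns=self._design_columns, fill_value=0.0)
        eta = self.intercept + x.to_numpy() @ self.coefficients.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=cohort.index,
                         name="propensity")


@dataclass
class MatchResult:
    """Outcome of 1:1 caliper matching plus balance summaries."""
    pairs: list                      # (exposed_row_id, control_row_id)
    caliper_value: float             # width on the matching scale
    scores: pd.Series                # per-row propensity
    unmatched_exposed: list
    smd_before: pd.Series = None
    smd_after: pd.Series = None

    @property
    def matched_ids(self):
        return [i for pair in self.pairs for i in pair]


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix; categoricals one-hot against a reference."""
    cols = {}
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == bool or str(s.dtype) == "boolean":
            cols[cov] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(x for x in s.dropna().unique())
            ref = _CATEGORICAL_REFERENCE.get(cov, levels[0] if levels else None)
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = s.eq(lev).astype(float)
        else:
            cols[cov] = s.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_propensity(cohort: pd.DataFrame,
                   covariates=None,
                   exposure_col: str = "age_mismatched",
                   ridge: bool = False) -> PropensityModel:
    """Fit the logistic propensity model of exposure on the covariates.

    Categorical covariates are one-hot encoded against documented
    reference levels; constant columns are dropped with a warning.
    Perfect separation raises with advice to retry with ``ridge=True``
    (small L2 penalty).
    """
    y = cohort[exposure_col].astype(float)
    if y.nunique() < 2:
        raise ValueError("both exposure classes must be present")
    covariates = list(covariates or DEFAULT_PS_COVARIATES)
    x = _design_matrix(cohort, covariates)
    const = [c for c in x.columns if x[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant covariate columns: {const}",
                      UserWarning, stacklevel=2)
        x = x.drop(columns=const)
    xc = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            if ridge:
                res = sm.Logit(y, xc).fit_regularized(
                    alpha=1.0, L1_wt=0.0, disp=0)
            else:
                res = sm.Logit(y, xc).fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=xc.columns)
        if not np.all(np.isfinite(params)):
            raise PerfectSeparationError("non-finite coefficients")
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as exc:
        if ridge:
            raise RuntimeError(f"penalized propensity fit failed: {exc}")
        raise RuntimeError(
            "propensity model did not converge (possible perfect "
            "separation); retry with ridge=True for a penalized fit"
        ) from exc
    return PropensityModel(
        covariate_names=covariates,
        coefficients=params.drop("const"),
        intercept=float(params["const"]),
        _design_columns=list(x.columns),
    )


def match_1to1(scores: pd.Series,
               exposed: pd.Series,
               caliper: float = 0.1,
               seed: int = 0,
               caliper_scale: str = "score") -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Exposed rows are processed in a seeded random order; each is paired
    with its nearest not-yet-used control, provided the score distance
    is within the caliper.  ``caliper_scale`` is ``"score"`` (caliper is
    a raw propensity-score width, the default) or ``"logit"`` (caliper x
    SD of the logit of the score, matched on the logit scale).  Ties
    between equidistant controls break to the lowest row id.
    """
    scores = pd.Series(scores).astype(float)
    exposed = pd.Series(exposed).astype(bool).reindex(scores.index)
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("scores must lie strictly in (0, 1)")
    if caliper_scale == "logit":
        vals = np.log(scores / (1 - scores))
        width = caliper * float(np.std(vals, ddof=1)) if len(vals) > 1 else caliper
    elif caliper_scale == "score":
        vals = scores.copy()
        width = float(caliper)
    else:
        raise ValueError("caliper_scale must be 'score' or 'logit'")

    exp_ids = scores.index[exposed]
    # controls sorted by row id so that np.argmin tie-breaks to lowest id
    ctrl_ids = scores.index[~exposed].sort_values()
    if len(ctrl_ids) == 0:
        warnings.warn("no control rows available; empty match", UserWarning,
                      stacklevel=2)
        return MatchResult([], width, scores, list(exp_ids))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exp_ids))
    ctrl_vals = vals.loc[ctrl_ids].to_numpy()
    available = np.ones(len(ctrl_ids), dtype=bool)
    pairs, unmatched = [], []
    for j in order:
        eid = exp_ids[j]
        if not available.any():
            unmatched.append(eid)
            continue
        d = np.abs(ctrl_vals - vals.loc[eid])
        d[~available] = np.inf
        k = int(np.argmin(d))
        if d[k] <= width:
            pairs.append((eid, ctrl_ids[k]))
            available[k] = False
        else:
            unmatched.append(eid)
    return MatchResult(pairs, width, scores, unmatched)


def standardized_mean_difference(values_a, values_b,
                                 kind: str = "continuous") -> float:
    """Standardized mean difference between two samples.

    continuous: (mean_a - mean_b) / sqrt((var_a + var_b)/2), unbiased
    variances; binary: (p_a - p_b) / sqrt((p_a(1-p_a) + p_b(1-p_b))/2).
    Zero pooled variance with equal means is defined as 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
        diff = pa - pb
    elif kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >=2 observations per group")
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
        diff = a.mean() - b.mean()
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(diff / np.sqrt(pooled))


def _smd_one(cohort, cov, mask_a, mask_b) -> float:
    s = cohort[cov]
    if s.dtype == bool or str(s.dtype) == "boolean":
        return standardized_mean_difference(
            s[mask_a].astype(float), s[mask_b].astype(float), "binary")
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        # multi-level categorical: max |SMD| over indicator levels
        best = 0.0
        for lev in s.dropna().unique():
            smd = standardized_mean_difference(
                s[mask_a].eq(lev).astype(float),
                s[mask_b].eq(lev).astype(float), "binary")
            if abs(smd) > abs(best):
                best = smd
        return abs(best)
    return standardized_mean_difference(s[mask_a], s[mask_b], "continuous")


def balance_table(cohort: pd.DataFrame,
                  covariates=None,
                  exposure_col: str = "age_mismatched",
                  pairs=None) -> pd.DataFrame:
    """Per-covariate SMDs before and (if pairs given) after matching.

    Continuous and binary covariates report the signed SMD; multi-level
    categoricals report the maximum absolute SMD over indicator levels.
    """
    covariates = list(covariates or DEFAULT_PS_COVARIATES)
    exp = cohort[exposure_col].astype(bool)
    rows = {}
    for cov in covariates:
        before = _smd_one(cohort, cov, exp, ~exp)
        after = np.nan
        if pairs is not None:
            e_ids = [p[0] for p in pairs]
            c_ids = [p[1] for p in pairs]
            sub = cohort.loc[e_ids + c_ids]
            sub_exp = sub[exposure_col].astype(bool)
            after = _smd_one(sub, cov, sub_exp, ~sub_exp)
        rows[cov] = {"smd_before": before, "smd_after": after}
    return pd.DataFrame.from_dict(rows, orient="index")
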