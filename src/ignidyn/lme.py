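"""Linear mixed-effects models linking node-metastability to protein burden.

Two complementary models are fit with restricted maximum likelihood:

* whole-brain:  ``metastability ~ abeta * tau`` with a random intercept per
  subject — does burden predict a region's metastability once between-subject
  level differences are absorbed?
* RSN-level:  the three-way fixed interaction ``abeta * tau * RSN`` with a
  random intercept per subject plus random RSN offsets within subject —
  which networks carry the burden effects?  Subcortical rows are excluded.

The nested random-effect structure is fragile at small cohort sizes; when the
full specification fails to converge the fit falls back to the
random-intercept-only form and records the downgrade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import AlignmentError, ConvergenceError, ParameterError
from .ignition import IgnitionProfile
from .rsn import SUBCORT

log = logging.getLogger(__name__)

__all__ = ["LmeResult", "build_long_table", "fit_wholebrain_lme", "fit_rsn_lme", "rsn_effect"]

WHOLEBRAIN_FORMULA = "metastability ~ abeta_suvr * tau_suvr"
RSN_FORMULA = "metastability ~ abeta_suvr * tau_suvr * C(rsn)"


@dataclass
class LmeResult:
    """Fixed-effect table, variance components and fit diagnostics."""

    fixed: pd.DataFrame  # index = term; columns estimate, std_error, p_value
    random_variances: dict[str, float]
    loglike: float
    converged: bool
    formula: str
    random_structure: str
    pvalue_method: str = "wald-normal"
    _sm_result: object = field(default=None, repr=False)


def build_long_table(
    metastability: list[IgnitionProfile] | pd.DataFrame,
    burdens: dict[str, pd.DataFrame],
    labels: pd.Series | dict,
) -> pd.DataFrame:
    """Join metastability, burden and RSN labels into one row per subject×region.

    ``metastability`` is either a list of per-subject ignition profiles or an
    already-long DataFrame with columns subject_id/region_id/metastability.
    Rows with missing metastability are dropped (count logged).
    """
    if isinstance(metastability, pd.DataFrame):
        meta = metastability[["subject_id", "region_id", "metastability"]].copy()
    else:
        meta = pd.concat(
            [
                pd.DataFrame(
                    {
                        "subject_id": p.subject_id,
                        "region_id": p.region_ids,
                        "metastability": p.node_metastability,
                    }
                )
                for p in metastability
            ],
            ignore_index=True,
        )
    if meta.duplicated(["subject_id", "region_id"]).any():
        dup = meta[meta.duplicated(["subject_id", "region_id"])].iloc[0]
        raise AlignmentError(
            f"duplicate subject×region row: {dup['subject_id']}/{dup['region_id']}"
        )
    labels = pd.Series(labels, name="rsn")
    parts = []
    for sid, grp in meta.groupby("subject_id", sort=True):
        if sid not in burdens:
            raise AlignmentError(f"no burden table for subject {sid}")
        bt = burdens[sid]
        merged = grp.merge(bt, on="region_id", how="left", validate="one_to_one")
        missing = merged[merged["abeta_suvr"].isna()]["region_id"].tolist()
        if missing:
            raise AlignmentError(f"subject {sid}: burden missing for regions {missing[:5]}")
        parts.append(merged)
    table = pd.concat(parts, ignore_index=True)
    table["rsn"] = table["region_id"].map(labels)
    if table["rsn"].isna().any():
        unlabelled = table.loc[table["rsn"].isna(), "region_id"].unique().tolist()
        raise AlignmentError(f"regions without RSN label: {unlabelled[:5]}")
    n_missing = int(table["metastability"].isna().sum())
    if n_missing:
        log.info("dropping %d rows with missing metastability", n_missing)
        table = table.dropna(subset=["metastability"]).reset_index(drop=True)
    return table.sort_values(["subject_id", "region_id"], ignore_index=True)


def _package(result, formula: str, random_structure: str) -> LmeResult:
    fe = result.fe_params
    se = result.bse_fe
    p = 2 * sps.norm.sf(np.abs(fe / se))
    fixed = pd.DataFrame(
        {"estimate": fe, "std_error": se, "p_value": p}, index=fe.index
    )
    rand = {"residual_var": float(result.scale)}
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    if cov_re.size:
        rand["subject_intercept_var"] = float(cov_re[0, 0])
    for name, v in zip(result.model.exog_vc.names, np.atleast_1d(result.vcomp)):
        rand[f"vc_{name}"] = float(v)
    return LmeResult(
        fixed=fixed,
        random_variances=rand,
        loglike=float(result.llf),
        converged=bool(result.converged),
        formula=formula,
        random_structure=random_structure,
        _sm_result=result,
    )


def _fit_with_retries(model, methods=("lbfgs", "bfgs", "powell", "cg"), reml=True):
    """(RE)ML fit, cycling optimisers until one converges."""
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            try:
                result = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if result.converged and np.all(np.isfinite(result.fe_params)):
                with np.errstate(invalid="ignore"):
                    ok_se = np.all(np.isfinite(np.asarray(result.bse_fe)))
                if ok_se:
                    return result
    if last_exc is not None:
        raise ConvergenceError(f"mixed model did not converge: {last_exc}")
    return None


def fit_wholebrain_lme(
    table: pd.DataFrame, include_interaction: bool = True, reml: bool = True
) -> LmeResult:
    """Fit ``metastability ~ abeta * tau`` with a subject random intercept.

    ``include_interaction=False`` drops the Aβ×tau term (the nested null
    model); use ``reml=False`` when log-likelihoods of models with different
    fixed effects must be compared.
    """
    if table["subject_id"].nunique() < 3:
        raise ParameterError("need at least 3 subjects for a mixed model")
    formula = WHOLEBRAIN_FORMULA if include_interaction else "metastability ~ abeta_suvr + tau_suvr"
    model = smf.mixedlm(formula, table, groups=table["subject_id"])
    result = _fit_with_retries(model, reml=reml)
    if result is None:
        raise ConvergenceError("whole-brain mixed model did not converge")
    return _package(result, formula, "~1 | subject")


def fit_rsn_lme(table: pd.DataFrame, allow_fallback: bool = True) -> LmeResult:
    """Fit the RSN-level model with random RSN offsets within subject.

    Subcortical rows are removed first.  A table with a single RSN level
    collapses to the whole-brain model.  If the random-slope structure fails
    to converge and ``allow_fallback`` is set, the random-intercept-only
    model is fit instead and the downgrade recorded in ``random_structure``.
    """
    data = table[table["rsn"] != SUBCORT].copy()
    rsns = sorted(data["rsn"].unique())
    if len(rsns) < 2:
        return fit_wholebrain_lme(data)
    counts = data.groupby("rsn")["subject_id"].nunique()
    thin = counts[counts < 2]
    if len(thin):
        raise ParameterError(f"RSNs present in <2 subjects: {list(thin.index)}")
    model = smf.mixedlm(
        RSN_FORMULA,
        data,
        groups=data["subject_id"],
        re_formula="1",
        vc_formula={"rsn": "0 + C(rsn)"},
    )
    try:
        result = _fit_with_retries(model, methods=("lbfgs", "bfgs"))
    except ConvergenceError:
        result = None
    if result is None:
        if not allow_fallback:
            raise ConvergenceError("RSN mixed model did not converge")
        log.warning("RSN random-slope model did not converge; falling back to random intercept")
        model = smf.mixedlm(RSN_FORMULA, data, groups=data["subject_id"])
        result = _fit_with_retries(model)
        if result is None:
            raise ConvergenceError("RSN mixed model did not converge even after fallback")
        return _package(result, RSN_FORMULA, "~1 | subject (fallback)")
    return _package(result, RSN_FORMULA, "~1 + rsn | subject")


def rsn_effect(result: LmeResult, effect: str, rsn: str) -> tuple[float, float, float]:
    """Burden effect (estimate, std error, p) within one RSN, by contrast.

    ``effect`` is one of ``abeta``, ``tau`` or ``interaction``.  For the
    reference RSN level the contrast is the base term alone; for other levels
    it is base term + its interaction with that level.
    """
    base = {
        "abeta": "abeta_suvr",
        "tau": "tau_suvr",
        "interaction": "abeta_suvr:tau_suvr",
    }[effect]
    sm_res = result._sm_result
    names = list(sm_res.model.exog_names)
    L = np.zeros((1, len(names)))
    if base not in names:
        raise ParameterError(f"term {base!r} not in model")
    L[0, names.index(base)] = 1.0
    inter = f"{base}:C(rsn)[T.{rsn}]"
    if inter in names:
        L[0, names.index(inter)] = 1.0
    tt = sm_res.t_test(L)
    est = float(np.ravel(tt.effect)[0])
    se = float(np.ravel(np.asarray(tt.sd))[0])
    p = float(2 * sps.norm.sf(abs(est / se)))
    return est, se, p
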