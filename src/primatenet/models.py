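"""Directed-dyad design and linear mixed models for biography effects.

Every ordered within-group dyad (sender, receiver) contributes one row whose
response is an interaction index (one of the four layers, or their sum).
Fixed effects are the three sender->receiver attribute combinations —
origin (wild-caught / captive-born), predominant housing condition during
infancy (with / without conspecifics) and sex — each a four-level factor.
Random effects are a group intercept and a sender intercept nested within
group, acknowledging that the rows sharing a sender are not independent.

Model comparison follows standard mixed-model practice: the full model
(three fixed factors) is compared against the intercept-only null model by a
maximum-likelihood likelihood-ratio test; marginal (Type III) F tests with
Satterthwaite denominator degrees of freedom and Tukey-style pairwise
contrasts with Holm-Bonferroni adjustment are computed on the REML fit.
The numerical solver is statsmodels' ``MixedLM``; this module owns the
design construction, the comparison logic, the Satterthwaite approximation
and the contrast families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from primatenet.scan_data import Biography

__all__ = [
    "RESPONSES",
    "REFERENCE_LEVELS",
    "combo_label",
    "build_dyad_table",
    "ModelResult",
    "fit_models",
    "posthoc_contrasts",
    "vif_check",
]

from primatenet.indices import LAYERS

RESPONSES = LAYERS + ("aggregated",)
FACTORS = ("origin_combo", "phc_combo", "sex_combo")

#: Baselines the contrasts are phrased against.
REFERENCE_LEVELS = {
    "origin_combo": "captive->captive",
    "phc_combo": "with->with",
    "sex_combo": "F->F",
}


def combo_label(sender_attr: str, receiver_attr: str) -> str:
    """Sender-first attribute combination label, e.g. ``wild->captive``."""
    if not sender_attr or not receiver_attr:
        raise ValueError("attributes must be nonempty")
    return f"{sender_attr}->{receiver_attr}"


def build_dyad_table(
    roster: list[Biography], index_table: pd.DataFrame
) -> pd.DataFrame:
    """One row per ordered within-group dyad with combos, indices and their sum.

    ``index_table`` is the long-format output of
    :func:`primatenet.indices.compute_indices`.
    """
    by_id = {b.id: b for b in roster}
    missing = set(index_table["sender"]) | set(index_table["receiver"])
    missing -= set(by_id)
    if missing:
        raise ValueError(f"index table references ids missing from roster: {sorted(missing)}")
    wide = index_table.pivot_table(
        index=["group", "sender", "receiver"], columns="layer", values="index"
    ).reset_index()
    for layer in LAYERS:
        if layer not in wide.columns:
            raise ValueError(f"index table lacks layer {layer!r}")
    rows = []
    for r in wide.itertuples():
        s, rcv = by_id[r.sender], by_id[r.receiver]
        if s.group != rcv.group:
            raise ValueError(f"cross-group dyad {r.sender}->{r.receiver}")
        row = {
            "group": r.group,
            "sender": r.sender,
            "receiver": r.receiver,
            "origin_combo": combo_label(s.origin, rcv.origin),
            "phc_combo": combo_label(s.phc_infant, rcv.phc_infant),
            "sex_combo": combo_label(s.sex, rcv.sex),
        }
        for layer in LAYERS:
            row[layer] = getattr(r, layer)
        row["aggregated"] = sum(row[layer] for layer in LAYERS)
        rows.append(row)
    table = pd.DataFrame(rows)
    for factor in FACTORS:
        ref = REFERENCE_LEVELS[factor]
        observed = sorted(table[factor].unique())
        cats = ([ref] if ref in observed else []) + [l for l in observed if l != ref]
        if len(cats) < len(_all_levels(factor)):
            absent = sorted(set(_all_levels(factor)) - set(cats))
            warnings.warn(
                f"{factor}: levels {absent} unobserved and dropped from the design",
                stacklevel=2,
            )
        table[factor] = pd.Categorical(table[factor], categories=cats)
    return table


def _all_levels(factor: str) -> list[str]:
    pairs = {
        "origin_combo": ("wild", "captive"),
        "phc_combo": ("with", "without"),
        "sex_combo": ("M", "F"),
    }[factor]
    return [combo_label(a, b) for a in pairs for b in pairs]


# ---------------------------------------------------------------------------
# REML machinery for Satterthwaite degrees of freedom


class _MarginalModel:
    """Marginal covariance Sigma(theta) = v_g J + v_s Z_s Z_s' + s2 I per group."""

    def __init__(self, data: pd.DataFrame, exog: np.ndarray, endog: np.ndarray):
        self.groups = data["group"].to_numpy()
        self.X = exog
        self.y = endog
        self.blocks = []
        for g in pd.unique(self.groups):
            mask = self.groups == g
            senders = pd.get_dummies(data.loc[mask, "sender"]).to_numpy(dtype=float)
            self.blocks.append((mask, senders))

    def sigma(self, mask: np.ndarray, zs: np.ndarray, theta: np.ndarray) -> np.ndarray:
        v_g, v_s, s2 = theta
        n = int(mask.sum())
        return v_g * np.ones((n, n)) + v_s * zs @ zs.T + s2 * np.eye(n)

    def beta_cov(self, theta: np.ndarray) -> np.ndarray:
        xtvx = 0.0
        for mask, zs in self.blocks:
            sigma_inv = np.linalg.inv(self.sigma(mask, zs, theta))
            xg = self.X[mask]
            xtvx = xtvx + xg.T @ sigma_inv @ xg
        return np.linalg.inv(xtvx)

    def reml_loglike(self, theta: np.ndarray) -> float:
        if (theta < 0).any() or theta[2] <= 0:
            return -np.inf
        logdet_sigma = 0.0
        xtvx = 0.0
        xtvy = 0.0
        ytvy = 0.0
        for mask, zs in self.blocks:
            sigma = self.sigma(mask, zs, theta)
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0:
                return -np.inf
            logdet_sigma += ld
            sigma_inv = np.linalg.inv(sigma)
            xg, yg = self.X[mask], self.y[mask]
            xtvx = xtvx + xg.T @ sigma_inv @ xg
            xtvy = xtvy + xg.T @ sigma_inv @ yg
            ytvy += float(yg @ sigma_inv @ yg)
        sign, ld_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - float(beta @ xtvy)
        return -0.5 * (logdet_sigma + ld_x + rss)

    def refine_theta(self, theta0: np.ndarray) -> np.ndarray:
        """Polish the variance estimates against this module's profiled REML
        criterion so that subsequent derivatives are taken at its optimum."""
        from scipy.optimize import minimize

        floor = max(float(theta0[2]), 1e-10)

        def nll(t: np.ndarray) -> float:
            return -self.reml_loglike(np.maximum(t, 0.0))

        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8 * floor, "fatol": 1e-10, "maxiter": 2000})
        theta = np.maximum(res.x, 0.0)
        return theta if np.isfinite(self.reml_loglike(theta)) else theta0

    def _steps(self, theta: np.ndarray) -> np.ndarray:
        # relative steps large enough to rise above double-precision noise in
        # the log-likelihood second differences
        return np.maximum(0.05 * np.abs(theta), 1e-4 * max(theta[2], 1e-8))

    def ml_loglike(self, theta: np.ndarray) -> float:
        """Profiled (beta maximised out) ML log-likelihood, constants included."""
        if (theta < 0).any() or theta[2] <= 0:
            return -np.inf
        n = len(self.y)
        logdet_sigma = 0.0
        xtvx = 0.0
        xtvy = 0.0
        ytvy = 0.0
        for mask, zs in self.blocks:
            sigma = self.sigma(mask, zs, theta)
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0:
                return -np.inf
            logdet_sigma += ld
            sigma_inv = np.linalg.inv(sigma)
            xg, yg = self.X[mask], self.y[mask]
            xtvx = xtvx + xg.T @ sigma_inv @ xg
            xtvy = xtvy + xg.T @ sigma_inv @ yg
            ytvy += float(yg @ sigma_inv @ yg)
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return -np.inf
        rss = ytvy - float(beta @ xtvy)
        return -0.5 * (n * np.log(2 * np.pi) + logdet_sigma + rss)

    def refine_ml_llf(self, theta0: np.ndarray) -> float:
        """Best profiled ML log-likelihood reachable from ``theta0``."""
        from scipy.optimize import minimize

        res = minimize(lambda t: -self.ml_loglike(np.maximum(t, 0.0)), theta0,
                       method="Nelder-Mead",
                       options={"fatol": 1e-10, "maxiter": 2000})
        return max(self.ml_loglike(np.maximum(res.x, 0.0)), self.ml_loglike(theta0))

    def theta_cov(self, theta: np.ndarray) -> np.ndarray | None:
        """Asymptotic covariance of the variance parameters from the observed
        information of the REML criterion (numerical Hessian)."""
        k = len(theta)
        h = self._steps(theta)
        hess = np.zeros((k, k))

        def f(t: np.ndarray) -> float:
            return self.reml_loglike(np.maximum(t, 0.0))

        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                else:
                    val = (
                        f(theta + ei + ej) - f(theta + ei - ej)
                        - f(theta - ei + ej) + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        if not np.isfinite(hess).all():
            return None
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(cov).all() or (np.diag(cov) < 0).any():
            return None
        return cov

    def satterthwaite_df(self, contrast: np.ndarray, theta: np.ndarray,
                         theta_cov: np.ndarray | None) -> float:
        """Satterthwaite df for a single contrast c'beta."""
        n, p = self.X.shape
        resid_df = n - p
        if theta_cov is None:
            return float(resid_df)
        h = self._steps(theta)
        f0 = float(contrast @ self.beta_cov(theta) @ contrast)
        grad = np.zeros(len(theta))
        for i in range(len(theta)):
            ei = np.zeros(len(theta)); ei[i] = h[i]
            up = float(contrast @ self.beta_cov(np.maximum(theta + ei, 0.0)) @ contrast)
            dn = float(contrast @ self.beta_cov(np.maximum(theta - ei, 0.0)) @ contrast)
            grad[i] = (up - dn) / (2 * h[i])
        denom = float(grad @ theta_cov @ grad)
        if denom <= 0:
            return float(resid_df)
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, resid_df))


@dataclass
class ModelResult:
    """Everything the dyadic mixed-model analysis reports for one response."""

    response: str
    n_obs: int
    converged: bool
    singular: bool
    degenerate: bool = False
    llf_full_ml: float = np.nan
    llf_null_ml: float = np.nan
    lrt_stat: float = np.nan
    lrt_df: int = 0
    lrt_p: float = np.nan
    anova: pd.DataFrame | None = None  # per factor: F, num_df, den_df, p
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    fixed_effects: pd.DataFrame | None = None  # coef, se per parameter
    level_means: dict[str, pd.Series] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def full_beats_null(self) -> bool:
        return bool(np.isfinite(self.lrt_p) and self.lrt_p < 0.05)


def _fit_mixedlm(formula: str, data: pd.DataFrame, reml: bool):
    model = smf.mixedlm(
        formula,
        data,
        groups=data["group"],
        re_formula="1",
        vc_formula={"sender": "0 + C(sender)"},
    )
    caught: list[str] = []
    res = None
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for method in ("lbfgs", "cg", "powell"):
            try:
                res = model.fit(reml=reml, method=method)
            except Exception:
                continue
            if getattr(res, "converged", False):
                break
        if res is None:
            raise RuntimeError("all mixed-model optimizers failed")
        for w in wlist:
            if issubclass(w.category, (ConvergenceWarning, UserWarning, RuntimeWarning)):
                caught.append(str(w.message))
    return model, res, caught


def _factor_selector(param_names: list[str], factor: str) -> np.ndarray:
    idx = [i for i, name in enumerate(param_names) if name.startswith(factor)]
    L = np.zeros((len(idx), len(param_names)))
    for row, i in enumerate(idx):
        L[row, i] = 1.0
    return L


def _param_level(name: str) -> str:
    # patsy names look like "origin_combo[T.wild->wild]"
    return name.split("[T.", 1)[1].rstrip("]") if "[T." in name else name


def fit_models(dyad_table: pd.DataFrame, response: str) -> ModelResult:
    """Fit the full and null dyadic mixed models for one response.

    Full model: ``response ~ origin_combo + phc_combo + sex_combo`` with a
    random group intercept and sender nested within group; null model keeps
    only the intercept and the random effects.  Full-vs-null is a
    likelihood-ratio test on ML fits; Type III F tests (Satterthwaite
    denominator df), pairwise contrasts and VIFs come from the REML fit.
    Degenerate responses (zero variance) are flagged, never raised.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    if dyad_table["group"].nunique() < 2:
        raise ValueError("need at least two groups for the nested random design")
    if dyad_table.groupby("group")["sender"].nunique().min() < 3:
        raise ValueError("each group needs at least three senders")
    data = dyad_table.copy()
    y_raw = data[response].astype(float)
    result = ModelResult(response=response, n_obs=len(data), converged=True, singular=False)

    if np.isclose(y_raw.var(ddof=0), 0.0):
        result.degenerate = True
        result.converged = False
        result.warnings.append("response is constant; model not fitted")
        return result

    # standardise internally so the optimizer sees O(1) variances; the LRT,
    # F statistics, z scores and Satterthwaite dfs are scale-invariant, and
    # reported estimates are rescaled back to index units
    y_sd = float(y_raw.std(ddof=0))
    data["_y"] = y_raw / y_sd

    fixed = " + ".join(FACTORS)
    try:
        _, full_ml, w1 = _fit_mixedlm(f"_y ~ {fixed}", data, reml=False)
        _, null_ml, w2 = _fit_mixedlm("_y ~ 1", data, reml=False)
        model_reml, full_reml, w3 = _fit_mixedlm(f"_y ~ {fixed}", data, reml=True)
    except Exception as exc:  # pragma: no cover - solver failure surface
        result.converged = False
        result.warnings.append(f"solver failed: {exc}")
        return result
    result.warnings.extend(w1 + w2 + w3)
    result.converged = bool(
        getattr(full_ml, "converged", True) and getattr(null_ml, "converged", True)
        and getattr(full_reml, "converged", True)
    )

    # --- full vs null (ML likelihood ratio), polished against the profiled
    # ML criterion so optimizer slack cannot inflate the statistic
    def _theta_of(fit) -> np.ndarray:
        return np.array(
            [float(np.asarray(fit.cov_re).ravel()[0]),
             float(np.asarray(fit.vcomp).ravel()[0]) if len(fit.vcomp) else 0.0,
             float(fit.scale)]
        )

    full_marg = _MarginalModel(data, full_ml.model.exog, full_ml.model.endog)
    null_marg = _MarginalModel(data, null_ml.model.exog, null_ml.model.endog)
    llf_full = max(float(full_ml.llf), full_marg.refine_ml_llf(_theta_of(full_ml)))
    llf_null = max(float(null_ml.llf), null_marg.refine_ml_llf(_theta_of(null_ml)))
    if llf_full < llf_null:  # optimizer slip: the null is nested in the full
        result.warnings.append("full ML fit below null; LRT clipped at 0")
        llf_full = llf_null
    result.llf_full_ml, result.llf_null_ml = llf_full, llf_null
    k_fixed = len([n for n in full_ml.fe_params.index])
    result.lrt_df = k_fixed - 1
    result.lrt_stat = 2.0 * (llf_full - llf_null)
    result.lrt_p = float(stats.chi2.sf(result.lrt_stat, result.lrt_df))

    # --- REML machinery
    fe = full_reml.fe_params
    fe_names = list(fe.index)
    vcov = np.asarray(full_reml.cov_params())[: len(fe_names), : len(fe_names)]
    theta = np.array(
        [float(np.asarray(full_reml.cov_re).ravel()[0]),
         float(np.asarray(full_reml.vcomp).ravel()[0]) if len(full_reml.vcomp) else 0.0,
         float(full_reml.scale)]
    )
    result.singular = bool((theta[:2] < 1e-8 * theta[2]).any())
    marginal = _MarginalModel(data, model_reml.exog, model_reml.endog)
    theta = marginal.refine_theta(theta)
    theta_cov = marginal.theta_cov(theta)
    if theta_cov is None:
        result.warnings.append(
            "variance-parameter information singular; residual df used"
        )

    result.fixed_effects = pd.DataFrame(
        {"coef": fe.values * y_sd, "se": np.sqrt(np.diag(vcov)) * y_sd}, index=fe_names
    )

    # --- Type III F with Satterthwaite denominator df
    anova_rows = []
    for factor in FACTORS:
        L = _factor_selector(fe_names, factor)
        q = L.shape[0]
        if q == 0:
            continue
        lvl = L @ fe.values
        lvcovl = L @ vcov @ L.T
        fstat = float(lvl @ np.linalg.solve(lvcovl, lvl)) / q
        # decompose the q-df test into independent 1-df contrasts, get a
        # Satterthwaite df for each, and combine them (lmerTest-style)
        vals, vecs = np.linalg.eigh(lvcovl)
        dfs = []
        for col in range(q):
            c = vecs[:, col] @ L
            dfs.append(marginal.satterthwaite_df(c, theta, theta_cov))
        dfs = np.asarray(dfs)
        usable = dfs[dfs > 2]
        if len(usable) == q:
            e_sum = float((dfs / (dfs - 2)).sum())
            den_df = 2 * e_sum / (e_sum - q) if e_sum > q else float(len(data) - len(fe_names))
        else:
            den_df = float(len(data) - len(fe_names))
        pval = float(stats.f.sf(fstat, q, den_df))
        anova_rows.append({"factor": factor, "F": fstat, "num_df": q,
                           "den_df": den_df, "p": pval})
    result.anova = pd.DataFrame(anova_rows).set_index("factor")

    # --- pairwise contrasts (Tukey family) with Holm adjustment, per factor
    for factor in FACTORS:
        tab = _pairwise_contrasts(data, factor, fe_names, fe.values, vcov)
        tab["estimate"] *= y_sd
        tab["se"] *= y_sd
        result.contrasts[factor] = tab

    # --- estimated level means (reference level absorbed in the intercept)
    for factor in FACTORS:
        levels = list(data[factor].cat.categories)
        means = {}
        for lvl_name in levels:
            means[lvl_name] = y_sd * (
                float(fe.values[0])
                + _coef_for(fe_names, fe.values, factor, lvl_name)
            )
        result.level_means[factor] = pd.Series(means)

    result.vif = vif_check(dyad_table)
    return result


def _coef_for(names: list[str], coefs: np.ndarray, factor: str, level: str) -> float:
    for i, name in enumerate(names):
        if name.startswith(factor) and _param_level(name) == level:
            return float(coefs[i])
    return 0.0  # reference level


def _pairwise_contrasts(
    data: pd.DataFrame,
    factor: str,
    fe_names: list[str],
    coefs: np.ndarray,
    vcov: np.ndarray,
) -> pd.DataFrame:
    levels = list(data[factor].cat.categories)
    rows = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            c = np.zeros(len(fe_names))
            for k, name in enumerate(fe_names):
                if name.startswith(factor):
                    lvl = _param_level(name)
                    if lvl == lb:
                        c[k] = 1.0
                    elif lvl == la:
                        c[k] = -1.0
            est = float(c @ coefs)
            se = float(np.sqrt(c @ vcov @ c))
            z = est / se if se > 0 else np.nan
            rows.append({"contrast": f"{lb} vs {la}", "estimate": est, "se": se,
                         "z": z, "p_raw": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p_raw"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_raw"], method="holm")[1]
        out["p_holm"] = adj
    return out


def posthoc_contrasts(result: ModelResult, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of one factor, Holm-adjusted."""
    if factor not in result.contrasts:
        raise ValueError(f"factor {factor!r} not in fitted model")
    return result.contrasts[factor]


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment (monotone, capped at 1)."""
    return list(multipletests(p_values, method="holm")[1])


def vif_check(dyad_table: pd.DataFrame) -> dict[str, float]:
    """Generalised VIF per categorical factor, on the fixed-effect design.

    Uses the determinant formula on the predictor correlation matrix and
    reports GVIF^(1/(2 df)) squared, i.e. GVIF^(1/df), comparable to
    conventional single-coefficient VIF thresholds.  Perfectly aliased
    factors raise an error naming the pair.
    """
    blocks: dict[str, np.ndarray] = {}
    for factor in FACTORS:
        d = pd.get_dummies(dyad_table[factor], drop_first=True).to_numpy(dtype=float)
        if d.shape[1] == 0:
            raise ValueError(f"factor {factor} has a single level; no VIF defined")
        blocks[factor] = d
    for i, fa in enumerate(FACTORS):
        for fb in FACTORS[i + 1 :]:
            combined = np.hstack([blocks[fa], blocks[fb]])
            centred = combined - combined.mean(axis=0)
            if np.linalg.matrix_rank(centred) < combined.shape[1]:
                raise ValueError(f"factors {fa} and {fb} are aliased")
    X = np.hstack([blocks[f] for f in FACTORS])
    R = np.corrcoef(X, rowvar=False)
    det_all = np.linalg.det(R)
    if det_all < 1e-12:
        raise ValueError("fixed design is collinear; VIF undefined")
    out: dict[str, float] = {}
    start = 0
    spans = {}
    for f in FACTORS:
        spans[f] = (start, start + blocks[f].shape[1])
        start += blocks[f].shape[1]
    for f in FACTORS:
        lo, hi = spans[f]
        own = list(range(lo, hi))
        rest = [i for i in range(X.shape[1]) if i not in own]
        gvif = (
            np.linalg.det(R[np.ix_(own, own)])
            * np.linalg.det(R[np.ix_(rest, rest)])
            / det_all
        )
        df = len(own)
        out[f] = float(gvif ** (1.0 / df))
    return out
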