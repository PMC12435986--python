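"""Linear mixed-model inference for per-trial kinematic features.

Each feature is modeled with language group (speaker/signer), movement
condition (non-communicative/communicative) and their interaction as fixed
effects, and crossed random effects for participants and test items. Models
are fitted by restricted maximum likelihood (REML) over an explicit,
deterministically descended *ladder* of random-effect structures (maximal →
drop slopes → intercepts only), mirroring the usual convergence-driven
simplification of maximal models.

Fixed effects use treatment coding with *speaker* and *non-communicative* as
reference levels, so the interaction coefficient is the signer-minus-speaker
difference of the communicative-minus-non-communicative shift.

Denominator degrees of freedom: the Kenward-Roger approximation is the
preferred method, but this implementation provides the Satterthwaite
approximation (computed from the curvature of the REML criterion) and every
report states which method was used. On balanced designs of the sizes
handled here the two agree closely. p-values are Bonferroni-multiplied by
the declared family size and deliberately left uncapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

from .trajectory import KinesigError

DEFAULT_FAMILY_SIZE = 7  # number of kinematic outcomes tested together


class ModelError(KinesigError):
    """No random-effect structure on the ladder could be fitted."""


class ContractError(KinesigError):
    """Operation called on a model that does not support it."""


# random-effect structure ladders, maximal first. "pair" is a random
# intercept for the trial pair (participant × item × session × trial): the
# two conditions of a pair share the item's spatial path, so their features
# are correlated beyond what participant and item intercepts capture, and
# omitting the pair term badly miscalibrates the condition contrasts.
LADDER_INTERACTION = (
    ("participant", "item", "pair", "participant_condition", "item_condition"),
    ("participant", "item", "pair", "participant_condition"),
    ("participant", "item", "pair"),
    ("participant", "item"),
    ("participant",),
)
LADDER_GROUP_ONLY = (
    ("participant", "item"),
    ("participant",),
)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, fixed-effect formula and random-effect ladder."""

    outcome: str
    fixed: str = "group*condition"  # or "group"
    ladder: tuple = LADDER_INTERACTION
    df_method: str = "kenward_roger"  # falls back to satterthwaite (reported)
    bonferroni_family_size: int = DEFAULT_FAMILY_SIZE

    def validate(self) -> None:
        if self.fixed not in ("group*condition", "group"):
            raise ContractError(f"unsupported fixed formula {self.fixed!r}")
        if not self.ladder:
            raise ContractError("random-effect ladder must be non-empty")
        if self.bonferroni_family_size < 1:
            raise ContractError("bonferroni_family_size must be >= 1")
        if self.df_method not in ("kenward_roger", "satterthwaite"):
            raise ContractError(f"unknown df_method {self.df_method!r}")


def _indicator(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    return np.column_stack([(values == lv).to_numpy(float) for lv in levels])


def _design_fixed(df: pd.DataFrame, fixed: str) -> tuple[np.ndarray, list[str]]:
    g = (df["group"] == "signer").to_numpy(float)
    if fixed == "group":
        X = np.column_stack([np.ones(len(df)), g])
        return X, ["Intercept", "group[signer]"]
    c = (df["condition"] == "communicative").to_numpy(float)
    X = np.column_stack([np.ones(len(df)), g, c, g * c])
    return X, [
        "Intercept",
        "group[signer]",
        "condition[communicative]",
        "group[signer]:condition[communicative]",
    ]


def _design_random(df: pd.DataFrame, names: tuple) -> dict[str, np.ndarray]:
    def comm() -> np.ndarray:
        return (df["condition"] == "communicative").to_numpy(float)

    out: dict[str, np.ndarray] = {}
    for name in names:
        if name == "participant":
            out[name] = _indicator(df["participant_id"])
        elif name == "item":
            out[name] = _indicator(df["item_id"])
        elif name == "participant_condition":
            out[name] = _indicator(df["participant_id"]) * comm()[:, None]
        elif name == "item_condition":
            out[name] = _indicator(df["item_id"]) * comm()[:, None]
        elif name == "pair":
            key = (
                df["participant_id"].astype(str)
                + ":" + df["item_id"].astype(str)
                + ":" + df["session"].astype(str)
                + ":" + df["trial_index"].astype(str)
            ) if "session" in df.columns else (
                df["participant_id"].astype(str) + ":" + df["item_id"].astype(str)
            )
            out[name] = _indicator(key)
        elif name == "item_group":
            sig = (df["group"] == "signer").to_numpy(float)
            out[name] = _indicator(df["item_id"]) * sig[:, None]
        else:
            raise ContractError(f"unknown random-effect component {name!r}")
    return out


class _REMLFit:
    """Dense variance-components REML fit: Σ = σe²I + Σk σk² Zk Zkᵀ."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: dict[str, np.ndarray]):
        self.y = y
        self.X = X
        self.Z = Z
        self.names = list(Z.keys())
        self.n, self.p = X.shape
        self.theta: np.ndarray | None = None  # log variances, components + residual
        self.converged = False

    def _sigma(self, theta: np.ndarray) -> np.ndarray:
        # clip keeps exploratory optimizer steps finite; the bounds are far
        # outside any plausible variance on these scales
        v = np.exp(np.clip(theta, -40.0, 40.0))
        sig = v[-1] * np.eye(self.n)
        for k, name in enumerate(self.names):
            Zk = self.Z[name]
            sig += v[k] * (Zk @ Zk.T)
        return sig

    def _neg2_reml(self, theta: np.ndarray) -> float:
        try:
            cf = cho_factor(self._sigma(theta), lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        SiX = cho_solve(cf, self.X)
        XtSiX = self.X.T @ SiX
        sgn, logdet_x = np.linalg.slogdet(XtSiX)
        if sgn <= 0:
            return 1e12
        beta = np.linalg.solve(XtSiX, SiX.T @ self.y)
        r = self.y - self.X @ beta
        quad = float(r @ cho_solve(cf, r))
        return logdet + logdet_x + quad

    def fit(self) -> bool:
        vy = float(np.var(self.y)) or 1.0
        k = len(self.names)
        start = np.log(np.concatenate((np.full(k, 0.2 * vy), [0.6 * vy])))
        res = optimize.minimize(
            self._neg2_reml,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        if not res.success:
            res2 = optimize.minimize(self._neg2_reml, res.x, method="Powell")
            res = res2 if res2.fun <= res.fun and res2.success else res
        self.theta = res.x
        self.converged = bool(res.success) or res.fun < 1e11
        return self.converged

    # ---- post-fit quantities -------------------------------------------------

    def beta_cov(self, theta: np.ndarray | None = None):
        theta = self.theta if theta is None else theta
        cf = cho_factor(self._sigma(theta), lower=True)
        SiX = cho_solve(cf, self.X)
        XtSiX = self.X.T @ SiX
        covb = np.linalg.inv(XtSiX)
        beta = covb @ (SiX.T @ self.y)
        return beta, covb

    def variances(self) -> dict[str, float]:
        v = np.exp(self.theta)
        out = {name: float(v[k]) for k, name in enumerate(self.names)}
        out["residual"] = float(v[-1])
        return out

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of θ̂ from the REML criterion's Hessian."""
        t0 = self.theta
        d = t0.size
        h = 1e-3 * (1.0 + np.abs(t0))
        H = np.empty((d, d))
        f0 = self._neg2_reml(t0)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d)
                ej = np.zeros(d)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (
                        self._neg2_reml(t0 + ei) - 2 * f0 + self._neg2_reml(t0 - ei)
                    ) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self._neg2_reml(t0 + ei + ej)
                        - self._neg2_reml(t0 + ei - ej)
                        - self._neg2_reml(t0 - ei + ej)
                        + self._neg2_reml(t0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        return 2.0 * np.linalg.pinv(H)

    def satterthwaite_df(self, c: np.ndarray, theta_cov: np.ndarray | None = None) -> float:
        """Satterthwaite denominator df for the contrast c'β."""

        def g(theta: np.ndarray) -> float:
            _, covb = self.beta_cov(theta)
            return float(c @ covb @ c)

        t0 = self.theta
        d = t0.size
        h = 1e-4 * (1.0 + np.abs(t0))
        grad = np.empty(d)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h[i]
            grad[i] = (g(t0 + ei) - g(t0 - ei)) / (2 * h[i])
        V = self._theta_cov() if theta_cov is None else theta_cov
        denom = float(grad @ V @ grad)
        g0 = g(t0)
        df_max = max(self.n - self.p, 1)
        if denom <= 0 or not np.isfinite(denom):
            return float(df_max)
        df = 2.0 * g0**2 / denom
        return float(np.clip(df, 1.0, df_max))


@dataclass
class ModelResult:
    """Fitted-model summary: per-term inference, cell means and diagnostics."""

    spec: ModelSpec
    terms: pd.DataFrame
    cell_means: pd.DataFrame | None
    converged_structure: str
    variances: dict
    df_method_used: str
    n_obs: int
    n_dropped: int
    _fit: _REMLFit = field(repr=False, default=None)
    _theta_cov: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "terms": self.terms.to_dict(orient="records"),
            "cell_means": None
            if self.cell_means is None
            else self.cell_means.to_dict(orient="records"),
            "converged_structure": self.converged_structure,
            "variances": self.variances,
            "df_method_used": self.df_method_used,
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
        }


def _infer_rows(
    fit: _REMLFit,
    contrasts: list[tuple[str, np.ndarray]],
    family: int,
    theta_cov: np.ndarray,
) -> pd.DataFrame:
    beta, covb = fit.beta_cov()
    rows = []
    for name, c in contrasts:
        est = float(c @ beta)
        se = float(np.sqrt(c @ covb @ c))
        df = fit.satterthwaite_df(c, theta_cov)
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        tcrit = sps.t.ppf(0.975, df)
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_corr": p * family,
            }
        )
    return pd.DataFrame(rows)


def fit_feature_model(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one feature's mixed model, descending the random-effect ladder.

    NaN outcomes are dropped listwise (count reported). Returns per-term
    estimates with Satterthwaite df, Bonferroni-corrected p-values and the
    ladder rung actually used.
    """
    spec.validate()
    df = table.copy()
    n_total = len(df)
    df = df[np.isfinite(df[spec.outcome].to_numpy(float))].reset_index(drop=True)
    n_dropped = n_total - len(df)
    y = df[spec.outcome].to_numpy(float)
    X, term_names = _design_fixed(df, spec.fixed)

    last_err = None
    for rung in spec.ladder:
        try:
            Z = _design_random(df, rung)
            fit = _REMLFit(y, X, Z)
            if fit.fit():
                theta_cov = fit._theta_cov()
                contrasts = [
                    (name, np.eye(X.shape[1])[k]) for k, name in enumerate(term_names)
                ]
                terms = _infer_rows(fit, contrasts, spec.bonferroni_family_size, theta_cov)
                cell_means = None
                if spec.fixed == "group*condition":
                    cell_means = _cell_means(fit, theta_cov)
                return ModelResult(
                    spec=spec,
                    terms=terms,
                    cell_means=cell_means,
                    converged_structure="+".join(rung),
                    variances=fit.variances(),
                    df_method_used="satterthwaite",
                    n_obs=len(df),
                    n_dropped=n_dropped,
                    _fit=fit,
                    _theta_cov=theta_cov,
                )
        except (np.linalg.LinAlgError, ValueError) as err:  # descend the ladder
            last_err = err
            continue
    raise ModelError(f"no random-effect structure converged for {spec.outcome}: {last_err}")


_CELLS = [
    ("speaker", "non_communicative", np.array([1.0, 0.0, 0.0, 0.0])),
    ("speaker", "communicative", np.array([1.0, 0.0, 1.0, 0.0])),
    ("signer", "non_communicative", np.array([1.0, 1.0, 0.0, 0.0])),
    ("signer", "communicative", np.array([1.0, 1.0, 1.0, 1.0])),
]


def _cell_means(fit: _REMLFit, theta_cov: np.ndarray) -> pd.DataFrame:
    beta, covb = fit.beta_cov()
    rows = []
    for group, cond, c in _CELLS:
        est = float(c @ beta)
        se = float(np.sqrt(c @ covb @ c))
        df = fit.satterthwaite_df(c, theta_cov)
        tcrit = sps.t.ppf(0.975, df)
        rows.append(
            {
                "group": group,
                "condition": cond,
                "mean": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "df": df,
            }
        )
    return pd.DataFrame(rows)


def posthoc_contrasts(result: ModelResult, family_size: int = 2) -> pd.DataFrame:
    """Within-group condition contrasts (communicative − non-communicative).

    Requires a model with the group × condition interaction; p-values are
    Bonferroni-multiplied by ``family_size`` (default: the two contrasts).
    """
    if result.spec.fixed != "group*condition" or result._fit is None:
        raise ContractError("post-hoc contrasts need a fitted interaction model")
    fit = result._fit
    cells = {(g, c): vec for g, c, vec in _CELLS}
    contrasts = [
        (
            f"{g}: communicative - non_communicative",
            cells[(g, "communicative")] - cells[(g, "non_communicative")],
        )
        for g in ("speaker", "signer")
    ]
    return _infer_rows(fit, contrasts, family_size, result._theta_cov)


def one_sample_group_test(
    values: np.ndarray, mu0: float = 0.0, family_size: int = 1
) -> dict:
    """One-sample t-test of trial-level values against ``mu0`` (df = n − 1)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ContractError("need at least 2 finite values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    se = sd / np.sqrt(n)
    degenerate = sd == 0.0
    df = n - 1
    if degenerate:
        t = 0.0 if mean == mu0 else float(np.sign(mean - mu0)) * np.inf
        p = 1.0 if mean == mu0 else 0.0
    else:
        t = (mean - mu0) / se
        p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return {
        "mean": mean,
        "se": se,
        "t": t,
        "df": df,
        "ci_low": mean - tcrit * se,
        "ci_high": mean + tcrit * se,
        "p_raw": p,
        "p_corr": p * family_size,
        "n": n,
        "degenerate": degenerate,
    }
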