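"""Average marginal effects, elasticities, bootstrap inference, heterogeneity.

The probit AME with respect to a log covariate v is the sample-average
derivative of the purchase probability, (1/n) sum_i phi(x_i'beta) * beta_v —
a semi-elasticity: the change in participation probability per unit change
of log premium (or log income). Dividing by the participation share E[vphi]
converts it to a proper elasticity: eps_p = AME(p) / E[vphi].

Because the structural probit consumes a generated regressor (the fitted log
premium), analytic standard errors are wrong across stages; all reported
uncertainty comes from a household-level nonparametric bootstrap that reruns
every stage per replicate.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError, EstimationError, InferenceError
from .survey_data import AnalysisSample
from .selection_estimators import (
    PriceEquationFit,
    ProbitFit,
    StructuralFit,
    fit_probit,
    fit_structural,
    heckit_price_equation,
    predict_log_price,
    reduced_design,
)

_VARIABLE_COLUMN = {"price": "ln_premium_hat", "income": "ln_income"}


def average_marginal_effect(fit: StructuralFit, variable: str) -> float:
    """Probit AME of the purchase probability w.r.t. a log covariate.

    ``variable`` is ``"price"`` (the instrumented log premium) or
    ``"income"`` (log household income).
    """
    if variable not in _VARIABLE_COLUMN:
        raise ConfigurationError(f"unknown variable {variable!r}; use 'price' or 'income'")
    if not fit.converged:
        raise EstimationError("AME requested from a non-converged fit")
    j = fit.names.index(_VARIABLE_COLUMN[variable])
    dens = stats.norm.pdf(fit.design @ fit.beta_hat)
    return float(dens.mean() * fit.beta_hat[j])


def compute_elasticity(ame: float, share: float) -> float:
    """Convert a semi-elasticity (AME) into an elasticity: ame / share."""
    if not (0 < share < 1):
        raise DomainError(f"participation share must be in (0, 1), got {share}")
    return float(ame) / float(share)


# --------------------------------------------------------------------------
# Full estimation chain on one sample
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ChainFit:
    """All three stage fits plus the headline scalars for one sample."""

    reduced: ProbitFit
    price: PriceEquationFit
    structural: StructuralFit
    lnp_hat: np.ndarray
    stats: dict[str, float]


def estimate_sample(sample: AnalysisSample, method: str = "probit") -> ChainFit:
    """Run reduced probit -> Mills-corrected price equation -> structural
    probit -> AMEs -> elasticities on one analysis sample."""
    reduced, price = heckit_price_equation(sample)
    Zd, _ = reduced_design(sample)
    lnp_hat = predict_log_price(price, Zd)
    structural = fit_structural(sample, lnp_hat, method=method)
    if method == "probit":
        ame_p = average_marginal_effect(structural, "price")
        ame_y = average_marginal_effect(structural, "income")
    else:  # linear probability: the coefficient is the marginal effect
        ame_p = structural.coefficient("ln_premium_hat")
        ame_y = structural.coefficient("ln_income")
    share = float(np.mean(sample.vphi))
    chain_stats = {
        "beta1": structural.coefficient("ln_premium_hat"),
        "beta2": structural.coefficient("ln_income"),
        "lambda_coef": price.lambda_coef,
        "ame_price": ame_p,
        "ame_income": ame_y,
        "participation_share": share,
        "elasticity_price": compute_elasticity(ame_p, share),
        "elasticity_income": compute_elasticity(ame_y, share),
        "n": float(sample.n),
        "n_purchasers": float(sample.n_purchasers),
    }
    return ChainFit(reduced, price, structural, lnp_hat, chain_stats)


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapResult:
    point: dict[str, float]
    se: dict[str, float]
    p_value: dict[str, float]
    replicates: pd.DataFrame
    n_requested: int
    n_failed: int

    def ci(self, key: str, level: float = 0.95, method: str = "percentile") -> tuple[float, float]:
        """Bootstrap confidence interval for one statistic.

        ``percentile`` (default) takes quantiles of the replicate
        distribution and is robust to its skewness and heavy tails;
        ``normal`` is the symmetric normal approximation around the point
        estimate.
        """
        if method == "percentile":
            if key not in self.replicates or self.replicates[key].dropna().empty:
                raise InferenceError(f"no replicates available for {key!r}")
            alpha = (1 - level) / 2
            q = self.replicates[key].quantile([alpha, 1 - alpha])
            return float(q.iloc[0]), float(q.iloc[1])
        if method == "normal":
            z = stats.norm.ppf(0.5 + level / 2)
            est, se = self.point[key], self.se[key]
            return est - z * se, est + z * se
        raise ConfigurationError(f"unknown interval method {method!r}")


def bootstrap_inference(
    pipeline_fn: Callable[[AnalysisSample], dict[str, float]],
    sample: AnalysisSample,
    B: int,
    seed: int,
) -> BootstrapResult:
    """Household-resampling bootstrap of an arbitrary full-chain statistic map.

    ``pipeline_fn`` receives a resampled :class:`AnalysisSample` and returns a
    flat dict of floats; every estimation stage must run inside it. Replicates
    that raise an estimation/design error (separation, lost variation...) are
    dropped and counted; more than 20% failures aborts.
    """
    if B < 50:
        raise ConfigurationError(f"bootstrap needs B >= 50, got {B}")
    point = pipeline_fn(sample)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, sample.n, size=sample.n)
        try:
            rows.append(pipeline_fn(sample.take(idx)))
        except (EstimationError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
    if n_failed > 0.2 * B:
        raise InferenceError(
            f"{n_failed}/{B} bootstrap replicates failed to estimate; "
            "the sample is too fragile for resampling inference"
        )
    reps = pd.DataFrame(rows)
    se = {k: float(reps[k].std(ddof=1)) if k in reps else np.nan for k in point}
    p_value = {}
    for k, est in point.items():
        s = se.get(k, np.nan)
        if not np.isfinite(s):
            p_value[k] = np.nan
        elif s == 0:
            p_value[k] = 1.0 if est == 0 else 0.0
        else:
            p_value[k] = float(2 * stats.norm.sf(abs(est) / s))
    return BootstrapResult(
        point=point,
        se=se,
        p_value=p_value,
        replicates=reps,
        n_requested=B,
        n_failed=n_failed,
    )


@dataclasses.dataclass
class ElasticityResult:
    """Headline results for one sample restriction, with bootstrap inference."""

    ame_price: float
    ame_income: float
    participation_share: float
    elasticity_price: float
    elasticity_income: float
    se: dict[str, float]
    p_value: dict[str, float]
    n: int
    n_purchasers: int
    bootstrap: BootstrapResult | None = None


def estimate_elasticities(
    sample: AnalysisSample,
    B: int = 200,
    seed: int = 0,
    method: str = "probit",
) -> ElasticityResult:
    """Point estimates plus bootstrap SEs/p-values for one sample."""

    def _fn(s: AnalysisSample) -> dict[str, float]:
        return estimate_sample(s, method=method).stats

    boot = bootstrap_inference(_fn, sample, B=B, seed=seed)
    pt = boot.point
    return ElasticityResult(
        ame_price=pt["ame_price"],
        ame_income=pt["ame_income"],
        participation_share=pt["participation_share"],
        elasticity_price=pt["elasticity_price"],
        elasticity_income=pt["elasticity_income"],
        se=boot.se,
        p_value=boot.p_value,
        n=int(pt["n"]),
        n_purchasers=int(pt["n_purchasers"]),
        bootstrap=boot,
    )


# --------------------------------------------------------------------------
# Heterogeneity
# --------------------------------------------------------------------------

GROUP_VARIABLES = ("head_age_group", "member_over_65", "child_under_5")

_FLAG_LABELS = {0: "no", 1: "yes"}


def _group_levels(sample: AnalysisSample, group_variable: str) -> tuple[np.ndarray, list[str]]:
    """Row labels and the ordered list of levels present (empty ones skipped)."""
    col = sample.df[group_variable]
    if group_variable in ("member_over_65", "child_under_5"):
        labels = col.map(_FLAG_LABELS).to_numpy()
        order = ["no", "yes"]
    else:
        labels = col.astype(str).to_numpy()
        order = [str(c) for c in col.cat.categories]
    present = []
    for lv in order:
        if (labels == lv).any():
            present.append(lv)
        else:
            warnings.warn(f"{group_variable} level {lv!r} is empty and was skipped")
    return labels, present


def heterogeneity_analysis(
    sample: AnalysisSample,
    lnp_hat: np.ndarray,
    group_variable: str,
) -> pd.DataFrame:
    """Group-specific semi-elasticities and elasticities.

    The structural probit is refit with the fitted log premium and log income
    each interacted with the group dummies (group-specific slopes, shared
    controls). Per group the AME averages the probit density over that
    group's rows, and the elasticity uses the group's own participation
    share. Also reports the group's mean observed premium among purchasers.
    """
    if group_variable not in GROUP_VARIABLES:
        raise ConfigurationError(
            f"unknown group variable {group_variable!r}; one of {GROUP_VARIABLES}"
        )
    lnp_hat = np.asarray(lnp_hat, dtype=float).ravel()
    labels, levels = _group_levels(sample, group_variable)
    if len(levels) < 2:
        raise EstimationError(
            f"heterogeneity needs >= 2 non-empty levels of {group_variable}"
        )
    cols = [np.ones(sample.n)]
    names = ["intercept"]
    for lv in levels:
        d = (labels == lv).astype(float)
        cols.append(lnp_hat * d)
        names.append(f"ln_premium_hat[{lv}]")
    for lv in levels:
        d = (labels == lv).astype(float)
        cols.append(sample.ln_income * d)
        names.append(f"ln_income[{lv}]")
    X_names = list(sample.x_names)
    Xc = sample.X
    if group_variable == "child_under_5" and "child_under_5" not in X_names:
        # group main effect is not among the standard controls; add it
        Xc = np.column_stack([Xc, sample.df["child_under_5"].to_numpy(float)])
        X_names = X_names + ["child_under_5"]
    design = np.column_stack(cols + [Xc])
    names = names + X_names
    fit = fit_probit(sample.vphi, design, names=names)
    dens = stats.norm.pdf(design @ fit.coefficients)

    rows = []
    premium = np.exp(sample.ln_premium)
    for lv in levels:
        mask = labels == lv
        share = float(sample.vphi[mask].mean())
        b_p = fit.coefficients[names.index(f"ln_premium_hat[{lv}]")]
        b_y = fit.coefficients[names.index(f"ln_income[{lv}]")]
        ame_p = float(dens[mask].mean() * b_p)
        ame_y = float(dens[mask].mean() * b_y)
        buyers = mask & (sample.vphi == 1)
        rows.append(
            {
                "group": lv,
                "n": int(mask.sum()),
                "n_purchasers": int(buyers.sum()),
                "mean_premium": float(np.nanmean(premium[buyers])) if buyers.any() else np.nan,
                "participation_share": share,
                "ame_price": ame_p,
                "elasticity_price": compute_elasticity(ame_p, share)
                if 0 < share < 1 else np.nan,
                "ame_income": ame_y,
                "elasticity_income": compute_elasticity(ame_y, share)
                if 0 < share < 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def heterogeneity_stats_fn(group_variable: str) -> Callable[[AnalysisSample], dict[str, float]]:
    """Full-chain heterogeneity statistics map for use with the bootstrap."""

    def _fn(s: AnalysisSample) -> dict[str, float]:
        _, price = heckit_price_equation(s)
        Zd, _ = reduced_design(s)
        tab = heterogeneity_analysis(s, predict_log_price(price, Zd), group_variable)
        out: dict[str, float] = {}
        for _, row in tab.iterrows():
            g = row["group"]
            for key in ("ame_price", "ame_income", "elasticity_price", "elasticity_income"):
                out[f"{key}[{g}]"] = row[key]
        return out

    return _fn


def test_group_equality(
    het: pd.DataFrame,
    boot: BootstrapResult,
    panel: str = "price",
) -> pd.DataFrame:
    """Pairwise equality tests of group AMEs from bootstrap replicates.

    For each pair of groups, the difference of AMEs with its bootstrap SE
    (SD of the replicate-wise difference) and a two-sided normal p-value.
    Pairs involving a single-observation group, or whose replicate columns
    are missing, are flagged untestable.
    """
    if panel not in ("price", "income"):
        raise ConfigurationError(f"panel must be 'price' or 'income', got {panel!r}")
    if boot.replicates.empty:
        raise InferenceError("no bootstrap replicates available for equality tests")
    key = f"ame_{panel}"
    groups = list(het["group"])
    if len(groups) < 2:
        raise InferenceError("equality tests need >= 2 groups")
    n_by_group = dict(zip(het["group"], het["n"]))
    point = dict(zip(het["group"], het[key]))
    rows = []
    for g1, g2 in combinations(groups, 2):
        c1, c2 = f"{key}[{g1}]", f"{key}[{g2}]"
        testable = (
            n_by_group[g1] > 1
            and n_by_group[g2] > 1
            and c1 in boot.replicates
            and c2 in boot.replicates
        )
        diff = point[g1] - point[g2]
        if testable:
            d = (boot.replicates[c1] - boot.replicates[c2]).dropna()
            se = float(d.std(ddof=1)) if len(d) > 1 else np.nan
            testable = np.isfinite(se) and se >= 0
        if testable and se > 0:
            p = float(2 * stats.norm.sf(abs(diff) / se))
        elif testable and se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            se, p = np.nan, np.nan
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "difference": diff,
                "se": se,
                "p_value": p,
                "testable": bool(testable),
            }
        )
    return pd.DataFrame(rows)
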