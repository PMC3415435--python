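"""Additive and synergistic DDI tests, multiplicity, enrichment, power.

The synergy statistic is the risk ratio

    RR = Risk12 / (Risk1 + Risk2),

where Risk1, Risk2 and Risk12 are the adjusted myopathy risks of the
substrate-alone, inhibitor-alone and joint exposure groups. Adjusted group
risks come from a three-level logistic regression followed by covariate
standardisation (g-computation): each episode's predicted risk is averaged
over the pooled covariate distribution with the group indicator set to each
level in turn, which reduces exactly to the raw group proportions when no
covariates are used. The null RR = 1 is tested by a Wald statistic for
log(RR) with a delta-method standard error (bootstrap available as an
alternative).

The additive model is a two-group logistic regression (joint vs substrate
alone); its null is "adding the inhibitor leaves risk unchanged", so unlike
the synergy test it confounds the inhibitor's own risk with interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

logger = logging.getLogger(__name__)

GROUPS = ("substrate_alone", "inhibitor_alone", "joint")

Covariate = Literal["age", "sex", "comeds"]
_COVARIATE_COLS = {"age": "age_at_anchor", "sex": "sex", "comeds": "comed_count"}


@dataclass
class DDITestResult:
    pair: tuple[str, str]
    model: Literal["additive", "synergistic"]
    risk1: float | None = None
    risk2: float | None = None
    risk12: float | None = None
    rr: float | None = None
    or_joint_vs_substrate: float | None = None
    p_value: float = np.nan
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    covariates_used: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def counts_label(self) -> str:
        """Render counts as "(m1/n1, m2/n2, m12/n12)"."""
        parts = []
        for g in GROUPS:
            if g in self.counts:
                m, n = self.counts[g]
                parts.append(f"{m}/{n}")
        return "(" + ", ".join(parts) + ")"


@dataclass(frozen=True)
class EnrichmentResult:
    enzyme: str
    n_sig_in: int
    n_in: int
    n_sig_out: int
    n_out: int
    p_value: float


def rr_statistic(risk1: float, risk2: float, risk12: float) -> float:
    """Synergy risk ratio RR = risk12 / (risk1 + risk2)."""
    denom = risk1 + risk2
    if denom <= 0:
        raise ValueError("risk1 + risk2 must be positive (undefined RR)")
    return risk12 / denom


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _group_counts(episodes: pd.DataFrame) -> dict[str, tuple[int, int]]:
    out = {}
    for g in GROUPS:
        sub = episodes[episodes["group"] == g]
        out[g] = (int(sub["outcome"].sum()), int(len(sub)))
    return out


def _design(episodes: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        col = _COVARIATE_COLS[c]
        if c == "sex":
            cols.append((episodes[col] == "F").astype(float).values)
        else:
            cols.append(episodes[col].astype(float).values)
    if not cols:
        return np.empty((len(episodes), 0))
    return np.column_stack(cols)


def _wald_logrr_from_counts(
    m1: int, n1: int, m2: int, n2: int, m12: int, n12: int
) -> tuple[float, float]:
    """(rr, two-sided p) for the covariate-free synergy test.

    Delta-method variance of log RR under independent binomial groups. Zero
    numerator or denominator events make the statistic degenerate; the test
    then does not reject (p = 1).
    """
    p1, p2, p12 = m1 / n1, m2 / n2, m12 / n12
    denom = p1 + p2
    if denom <= 0 or p12 <= 0:
        return (0.0 if denom > 0 else np.nan), 1.0
    rr = p12 / denom
    var = (1 - p12) / (n12 * p12) + (
        p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    ) / denom**2
    if var <= 0:  # all-ones degenerate groups
        return rr, 1.0
    z = np.log(rr) / np.sqrt(var)
    return rr, float(2 * sps.norm.sf(abs(z)))


def _check_groups(episodes: pd.DataFrame, required: Iterable[str]) -> None:
    present = set(episodes["group"].unique())
    for g in required:
        if g not in present or not len(episodes[episodes["group"] == g]):
            raise ValueError(f"exposure group '{g}' is empty")


def _pair_of(episodes: pd.DataFrame) -> tuple[str, str]:
    if "drug1" in episodes.columns and len(episodes):
        return (str(episodes["drug1"].iloc[0]), str(episodes["drug2"].iloc[0]))
    return ("drug1", "drug2")


# ---------------------------------------------------------------------------
# additive model
# ---------------------------------------------------------------------------

def fit_additive(
    episodes: pd.DataFrame,
    covariates: Sequence[Covariate] = (),
) -> DDITestResult:
    """Joint vs substrate-alone logistic regression (additive model).

    Reports the odds ratio for joint exposure and its two-sided Wald p-value.
    Downstream significance additionally requires OR > 1. With no covariates
    the fit is the closed-form 2x2 logit (identical to the regression MLE).
    """
    sub = episodes[episodes["group"].isin(["substrate_alone", "joint"])]
    _check_groups(sub, ["substrate_alone", "joint"])
    counts = _group_counts(episodes)
    result = DDITestResult(
        pair=_pair_of(episodes), model="additive",
        counts=counts, covariates_used=tuple(covariates),
    )
    if not covariates:
        m1, n1 = counts["substrate_alone"]
        m12, n12 = counts["joint"]
        a, b = m12, n12 - m12
        c, d = m1, n1 - m1
        flags: list[str] = []
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            flags.append("continuity_corrected")
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        result.or_joint_vs_substrate = float(np.exp(log_or))
        result.p_value = float(2 * sps.norm.sf(abs(log_or / se)))
        result.flags = tuple(flags)
        return result

    import statsmodels.api as sm

    X = np.column_stack(
        [np.ones(len(sub)), (sub["group"] == "joint").astype(float).values,
         _design(sub, covariates)]
    )
    y = sub["outcome"].astype(float).values
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        result.or_joint_vs_substrate = float(np.exp(fit.params[1]))
        result.p_value = float(fit.pvalues[1])
    except Exception:  # separation or non-convergence
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        result.or_joint_vs_substrate = float(np.exp(fit.params[1]))
        result.p_value = np.nan
        result.flags = ("separation_penalized_fallback",)
        logger.warning("additive fit for %s: separation; penalized fallback, no p-value",
                       result.pair)
    return result


# ---------------------------------------------------------------------------
# synergistic model
# ---------------------------------------------------------------------------

def fit_synergistic(
    episodes: pd.DataFrame,
    covariates: Sequence[Covariate] = (),
    method: Literal["delta", "bootstrap"] = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> DDITestResult:
    """Three-group synergy test with covariate standardisation.

    Fits outcome ~ group (+ covariates) by logistic regression, standardises
    group risks over the pooled covariate distribution, computes
    RR = Risk12/(Risk1+Risk2) and a two-sided Wald p-value for log RR
    (delta method on the standardised-risk scale, or a seeded bootstrap of
    the standard error).
    """
    _check_groups(episodes, GROUPS)
    counts = _group_counts(episodes)
    result = DDITestResult(
        pair=_pair_of(episodes), model="synergistic",
        counts=counts, covariates_used=tuple(covariates),
    )

    if not covariates:
        m1, n1 = counts["substrate_alone"]
        m2, n2 = counts["inhibitor_alone"]
        m12, n12 = counts["joint"]
        result.risk1, result.risk2, result.risk12 = m1 / n1, m2 / n2, m12 / n12
        rr, p = _wald_logrr_from_counts(m1, n1, m2, n2, m12, n12)
        result.rr = rr if np.isfinite(rr) else np.nan
        if method == "bootstrap":
            p = _bootstrap_p_from_counts(m1, n1, m2, n2, m12, n12, n_boot, seed)
        result.p_value = p
        return result

    import statsmodels.api as sm

    g2 = (episodes["group"] == "inhibitor_alone").astype(float).values
    g12 = (episodes["group"] == "joint").astype(float).values
    Z = _design(episodes, covariates)
    X = np.column_stack([np.ones(len(episodes)), g2, g12, Z])
    y = episodes["outcome"].astype(float).values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    beta, cov = fit.params, fit.cov_params()

    def standardized_risks(b: np.ndarray) -> np.ndarray:
        risks = []
        for level in range(3):
            Xg = X.copy()
            Xg[:, 1] = 1.0 if level == 1 else 0.0
            Xg[:, 2] = 1.0 if level == 2 else 0.0
            risks.append(float(np.mean(expit(Xg @ b))))
        return np.array(risks)

    r1, r2, r12 = standardized_risks(beta)
    result.risk1, result.risk2, result.risk12 = r1, r2, r12
    result.rr = rr_statistic(r1, r2, r12)

    # analytic gradient of the standardised risks wrt beta
    def risk_grads(b: np.ndarray) -> np.ndarray:
        grads = []
        for level in range(3):
            Xg = X.copy()
            Xg[:, 1] = 1.0 if level == 1 else 0.0
            Xg[:, 2] = 1.0 if level == 2 else 0.0
            mu = expit(Xg @ b)
            grads.append((mu * (1 - mu)) @ Xg / len(Xg))
        return np.array(grads)  # 3 x k

    G = risk_grads(beta)
    grad_logrr = G[2] / r12 - (G[0] + G[1]) / (r1 + r2)
    var = float(grad_logrr @ cov @ grad_logrr)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = []
        idx_by_group = {g: np.flatnonzero(episodes["group"].values == g) for g in GROUPS}
        for _ in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True)
                 for idx in idx_by_group.values()]
            )
            resampled = episodes.iloc[take]
            try:
                sub = fit_synergistic(resampled, covariates, method="delta")
                if sub.rr and sub.rr > 0:
                    boot.append(np.log(sub.rr))
            except Exception:
                continue
        se = float(np.std(boot, ddof=1)) if len(boot) > 1 else np.nan
        result.p_value = (
            float(2 * sps.norm.sf(abs(np.log(result.rr) / se)))
            if se and np.isfinite(se) and se > 0 else np.nan
        )
        return result
    if var <= 0 or result.rr <= 0:
        result.p_value = 1.0
        return result
    z = np.log(result.rr) / np.sqrt(var)
    result.p_value = float(2 * sps.norm.sf(abs(z)))
    return result


def _bootstrap_p_from_counts(
    m1: int, n1: int, m2: int, n2: int, m12: int, n12: int,
    n_boot: int, seed: int,
) -> float:
    """Seeded within-group binomial bootstrap of se(log RR)."""
    rr, _ = _wald_logrr_from_counts(m1, n1, m2, n2, m12, n12)
    if not rr or not np.isfinite(rr) or rr <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    b1 = rng.binomial(n1, m1 / n1, size=n_boot) / n1
    b2 = rng.binomial(n2, m2 / n2, size=n_boot) / n2
    b12 = rng.binomial(n12, m12 / n12, size=n_boot) / n12
    ok = (b1 + b2 > 0) & (b12 > 0)
    if ok.sum() < 2:
        return 1.0
    logrr = np.log(b12[ok] / (b1[ok] + b2[ok]))
    se = float(np.std(logrr, ddof=1))
    if se <= 0:
        return 1.0
    return float(2 * sps.norm.sf(abs(np.log(rr) / se)))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enzyme_enrichment(
    results: Sequence[DDITestResult],
    pair_enzyme_map: Mapping[tuple[str, str], Iterable[str]],
    threshold: float,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of significant pairs per enzyme.

    A pair is significant when p < threshold with effect direction > 1
    (RR for synergistic results, OR for additive). Each pair counts once per
    enzyme it maps to; the 2x2 table (significant x in-enzyme) is tested with
    a one-sided exact test.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sig: dict[tuple[str, str], bool] = {}
    for r in results:
        effect = r.rr if r.model == "synergistic" else r.or_joint_vs_substrate
        sig[r.pair] = bool(
            np.isfinite(r.p_value) and r.p_value < threshold
            and effect is not None and effect > 1
        )
    enzymes = sorted({e for v in pair_enzyme_map.values() for e in v})
    out = []
    for enzyme in enzymes:
        in_pairs = [p for p in sig if enzyme in set(pair_enzyme_map.get(p, ()))]
        out_pairs = [p for p in sig if p not in set(in_pairs)]
        n_in, n_out = len(in_pairs), len(out_pairs)
        n_sig_in = sum(sig[p] for p in in_pairs)
        n_sig_out = sum(sig[p] for p in out_pairs)
        table = [[n_sig_in, n_in - n_sig_in], [n_sig_out, n_out - n_sig_out]]
        _, p = sps.fisher_exact(table, alternative="greater")
        out.append(
            EnrichmentResult(
                enzyme=enzyme, n_sig_in=n_sig_in, n_in=n_in,
                n_sig_out=n_sig_out, n_out=n_out, p_value=float(p),
            )
        )
    return out


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    n_reps: int
    alpha: float


def power_simulation(
    n1: int,
    n2: int,
    n12: int,
    base_risks: tuple[float, float],
    rr_alt: float,
    alpha: float,
    n_reps: int = 2000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the synergistic test for a given design.

    Draws the three cohorts as independent binomials with risks
    (risk1, risk2, rr_alt*(risk1+risk2)) and counts rejections
    (two-sided Wald p < alpha with RR > 1). Reproducible under ``seed``;
    reports the Monte-Carlo standard error of the power estimate.
    """
    if min(n1, n2, n12) <= 0:
        raise ValueError("all group sizes must be positive")
    if n_reps < 100:
        logger.warning("n_reps=%d is small; power estimate will be noisy", n_reps)
    risk1, risk2 = base_risks
    risk12 = min(rr_alt * (risk1 + risk2), 1.0)
    rng = np.random.default_rng(seed)
    m1 = rng.binomial(n1, risk1, size=n_reps)
    m2 = rng.binomial(n2, risk2, size=n_reps)
    m12 = rng.binomial(n12, risk12, size=n_reps)
    p1, p2, p12 = m1 / n1, m2 / n2, m12 / n12
    denom = p1 + p2
    valid = (denom > 0) & (p12 > 0)
    rr = np.full(n_reps, np.nan)
    pval = np.ones(n_reps)
    d, q12 = denom[valid], p12[valid]
    rr_v = q12 / d
    var = (1 - q12) / (n12 * q12) + (
        p1[valid] * (1 - p1[valid]) / n1 + p2[valid] * (1 - p2[valid]) / n2
    ) / d**2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.log(rr_v) / np.sqrt(var), 0.0)
    pval[valid] = 2 * sps.norm.sf(np.abs(z))
    rr[valid] = rr_v
    reject = (pval < alpha) & (rr > 1)
    power = float(np.mean(reject))
    mc_se = float(np.sqrt(power * (1 - power) / n_reps))
    return PowerEstimate(power=power, mc_se=mc_se, n_reps=n_reps, alpha=alpha)
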