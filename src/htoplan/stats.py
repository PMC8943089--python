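"""Matched-cohort comparison pipeline.

Implements the analysis applied to the two treatment arms: propensity-score
nearest-neighbour matching on age, BMI and the angular deformity measures;
pooled two-sample and paired t-tests at alpha = 0.05; the accuracy band on
the post-operative weight-bearing line (50-75 % of plateau width, bounds
inclusive) with a Pearson chi-square comparison of band membership;
ordinary-least-squares regression of post-operative WBL% on MPTA; and a
noncentral-t post-hoc power routine.

Chi-square is computed without continuity correction; no multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .cohort import KneeRecord
from .errors import (
    ConfigError,
    DataError,
    DegenerateRegressionError,
    UndefinedTestError,
)

__all__ = [
    "MatchResult",
    "ComparisonReport",
    "propensity_match",
    "two_sample_t",
    "paired_t",
    "classify_accuracy",
    "chi_square_2x2",
    "linreg_wbl_on_mpta",
    "posthoc_power",
    "cohens_d",
    "build_report",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "bmi", "wbl", "jlca", "mpta", "pts")
ACCURACY_BAND = (50.0, 75.0)


# ---------------------------------------------------------------------------
# matching


@dataclass(frozen=True)
class MatchResult:
    """Greedy 1:1 nearest-neighbour match without replacement."""

    pairs: Tuple[Tuple[str, str], ...]
    scores: Dict[str, float]
    unmatched: Tuple[str, ...]
    method: str  # "propensity" or "euclidean" (separation fallback)
    smd_before: Dict[str, float]
    smd_after: Dict[str, float]


def _covariate_frame(
    records: Sequence[KneeRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.meas_pre is None:
            raise DataError(f"record {r.id} has no measured pre-operative values")
        row = {
            "id": r.id,
            "arm": r.arm,
            "age": r.age,
            "bmi": r.bmi,
            "wbl": r.meas_pre.wbl_percent,
            "jlca": r.meas_pre.jlca,
            "mpta": r.meas_pre.mpta,
            "pts": r.meas_pre.pts,
        }
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    cols = list(covariates)
    if df[cols].isna().any().any() or not np.isfinite(df[cols].to_numpy()).all():
        raise DataError("covariates contain non-finite values")
    return df


def _smd(df: pd.DataFrame, covariates: Sequence[str]) -> Dict[str, float]:
    """Standardized mean differences (treated minus control, pooled SD)."""
    t = df[df["arm"] == "noyes"]
    c = df[df["arm"] == "conventional"]
    out = {}
    for cov in covariates:
        sd = math.sqrt((t[cov].var(ddof=1) + c[cov].var(ddof=1)) / 2.0)
        out[cov] = float((t[cov].mean() - c[cov].mean()) / sd) if sd > 0 else 0.0
    return out


def propensity_match(
    records: Sequence[KneeRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    treated_arm: str = "noyes",
) -> MatchResult:
    """Match treated knees to controls on the propensity score.

    The score is a logistic regression of arm membership on the covariates;
    treated knees are processed in descending score order and each greedily
    takes the unused control with the nearest score.  Under perfect
    separation the match falls back to standardized Euclidean distance on
    the covariates (with a warning).
    """
    df = _covariate_frame(records, covariates)
    arms = set(df["arm"])
    if len(arms) != 2:
        raise DataError("matching needs exactly two arms")
    n_treated = int((df["arm"] == treated_arm).sum())
    if n_treated < 2 or len(df) - n_treated < 2:
        raise DataError("need at least two subjects per arm")

    X = sm.add_constant(df[list(covariates)].to_numpy())
    y = (df["arm"] == treated_arm).to_numpy(dtype=float)
    method = "propensity"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        score = np.asarray(fit.predict(X), dtype=float)
        if not np.all(np.isfinite(score)):
            raise ValueError("non-finite propensity scores")
    except Exception:
        warnings.warn(
            "propensity model separated or failed to converge; "
            "falling back to standardized Euclidean matching",
            stacklevel=2,
        )
        method = "euclidean"
        Z = df[list(covariates)].to_numpy()
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        score = np.zeros(len(df))

    scores = dict(zip(df.index, map(float, score)))
    treated = df.index[df["arm"] == treated_arm]
    controls = list(df.index[df["arm"] != treated_arm])
    if method == "propensity":
        order = sorted(treated, key=lambda i: -scores[i])
        dist = lambda t, c: abs(scores[t] - scores[c])  # noqa: E731
    else:
        zidx = {i: Z[k] for k, i in enumerate(df.index)}
        order = sorted(treated, key=lambda i: tuple(zidx[i]))  # deterministic
        dist = lambda t, c: float(np.linalg.norm(zidx[t] - zidx[c]))  # noqa: E731

    pairs: List[Tuple[str, str]] = []
    for t in order:
        if not controls:
            break
        best = min(controls, key=lambda c: (dist(t, c), c))
        pairs.append((t, best))
        controls.remove(best)
    matched_ids = {i for p in pairs for i in p}
    unmatched = tuple(i for i in df.index if i not in matched_ids)
    smd_before = _smd(df, covariates)
    smd_after = _smd(df.loc[sorted(matched_ids)], covariates)
    return MatchResult(
        tuple(pairs), scores, unmatched, method, smd_before, smd_after
    )


# ---------------------------------------------------------------------------
# elementary tests


def _check_finite(*arrays) -> None:
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.size and not np.all(np.isfinite(a)):
            raise DataError("input contains non-finite values")


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> Tuple[float, float]:
    """Two-sample t-test (pooled by default), two-sided.

    Zero variance in both samples with equal means returns (0, 1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs at least two observations")
    _check_finite(a, b)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def paired_t(pre: Sequence[float], post: Sequence[float]) -> Tuple[float, float]:
    """Paired t-test on pre/post values, two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise DataError("paired samples must have equal length")
    if len(pre) < 2:
        raise DataError("need at least two pairs")
    _check_finite(pre, post)
    d = post - pre
    if d.var(ddof=1) == 0.0:
        return (0.0, 1.0) if d.mean() == 0.0 else (math.inf, 0.0)
    t, p = sps.ttest_rel(pre, post)
    return float(t), float(p)


def classify_accuracy(
    wbl_percent: float, band: Tuple[float, float] = ACCURACY_BAND
) -> str:
    """Correction-accuracy label for a post-operative WBL crossing.

    ``under`` below the band, ``within`` inside it (bounds inclusive),
    ``over`` above it.
    """
    lo, hi = band
    if not math.isfinite(wbl_percent):
        raise DataError("WBL value must be finite")
    if wbl_percent < lo:
        return "under"
    if wbl_percent > hi:
        return "over"
    return "within"


def chi_square_2x2(counts: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    tab = np.asarray(counts)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise DataError("counts must form a nonnegative 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise UndefinedTestError("contingency table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def linreg_wbl_on_mpta(
    mpta: Sequence[float], wbl: Sequence[float]
) -> Tuple[float, float, float]:
    """OLS of WBL% on MPTA: (slope in %/degree, intercept, slope p-value)."""
    x = np.asarray(mpta, dtype=float)
    y = np.asarray(wbl, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need at least three paired observations")
    _check_finite(x, y)
    if x.var(ddof=1) == 0.0:
        raise DegenerateRegressionError("MPTA predictor is constant")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[1])


def posthoc_power(
    n1: int, n2: int, d: float, alpha: float = 0.05
) -> float:
    """Post-hoc power of a two-sided two-sample t-test, via noncentral t.

    ``d`` is Cohen's d; ``d = 0`` returns ``alpha`` (the type-I rate).
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("need n >= 2 per group")
    if d < 0:
        raise ConfigError("effect size d cannot be negative")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sp = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


# ---------------------------------------------------------------------------
# report


@dataclass
class MeasureBlock:
    """Pre/post comparison of one measure across the two arms."""

    measure: str
    pre_mean: Dict[str, float]
    pre_sd: Dict[str, float]
    post_mean: Dict[str, float]
    post_sd: Dict[str, float]
    p_between_pre: float
    p_between_post: float
    p_within: Dict[str, float]


@dataclass
class ComparisonReport:
    """Full matched-cohort comparison."""

    schema_version: str
    n_per_arm: Dict[str, int]
    blocks: Dict[str, MeasureBlock]
    accuracy_counts: Dict[str, Dict[str, int]]
    chi2_within_band: Tuple[float, float]
    regression: Dict[str, float]
    posthoc_power: float
    match: Optional[MatchResult] = None

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "n_per_arm": self.n_per_arm,
            "measures": {
                k: {
                    "pre_mean": b.pre_mean,
                    "pre_sd": b.pre_sd,
                    "post_mean": b.post_mean,
                    "post_sd": b.post_sd,
                    "p_between_pre": b.p_between_pre,
                    "p_between_post": b.p_between_post,
                    "p_within": b.p_within,
                }
                for k, b in self.blocks.items()
            },
            "accuracy_counts": self.accuracy_counts,
            "chi2_within_band": {
                "chi2": self.chi2_within_band[0],
                "p": self.chi2_within_band[1],
            },
            "regression": self.regression,
            "posthoc_power": self.posthoc_power,
        }
        if self.match is not None:
            d["matching"] = {
                "method": self.match.method,
                "n_pairs": len(self.match.pairs),
                "unmatched": list(self.match.unmatched),
                "smd_before": self.match.smd_before,
                "smd_after": self.match.smd_after,
            }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = []
        arms = list(self.n_per_arm)
        lines.append(
            "Matched-cohort comparison  ("
            + ", ".join(f"{a}: n={n}" for a, n in self.n_per_arm.items())
            + ")"
        )
        for name, b in self.blocks.items():
            lines.append(f"\n{name.upper()}")
            for phase, mean, sd, p in (
                ("pre ", b.pre_mean, b.pre_sd, b.p_between_pre),
                ("post", b.post_mean, b.post_sd, b.p_between_post),
            ):
                cells = "   ".join(
                    f"{a}: {mean[a]:6.1f} ± {sd[a]:4.1f}" for a in arms
                )
                lines.append(f"  {phase}  {cells}   p(between) = {p:.3f}")
            cells = "   ".join(f"{a}: p = {b.p_within[a]:.3f}" for a in arms)
            lines.append(f"  within-arm pre vs post   {cells}")
        lines.append("\nACCURACY (post-op WBL, band 50–75 % inclusive)")
        for a in arms:
            c = self.accuracy_counts[a]
            lines.append(
                f"  {a}: under {c['under']}, within {c['within']}, over {c['over']}"
            )
        chi2, p = self.chi2_within_band
        lines.append(f"  within-band chi-square = {chi2:.3f}, p = {p:.3f}")
        r = self.regression
        lines.append(
            f"\nREGRESSION post-op WBL% on MPTA: slope {r['slope']:.2f} %/deg, "
            f"intercept {r['intercept']:.1f}, p = {r['p']:.3g}"
        )
        lines.append(f"POST-HOC POWER (post-op WBL contrast): {self.posthoc_power:.2f}")
        return "\n".join(lines)


def _measured(records: Iterable[KneeRecord], attr: str, phase: str) -> np.ndarray:
    vals = []
    for r in records:
        m = r.meas_pre if phase == "pre" else r.meas_post
        if m is None:
            raise DataError(f"record {r.id} lacks measured {phase} values")
        vals.append(getattr(m, attr))
    return np.asarray(vals, dtype=float)


def build_report(
    records: Sequence[KneeRecord],
    match: Optional[MatchResult] = None,
    power_measure: str = "wbl_percent",
) -> ComparisonReport:
    """Assemble the full comparison from a cohort (optionally matched).

    When a :class:`MatchResult` is given only matched subjects enter the
    comparison.  The post-hoc power is that of the between-arm post-operative
    contrast of ``power_measure`` at the observed effect size.
    """
    if match is not None:
        keep = {i for p in match.pairs for i in p}
        records = [r for r in records if r.id in keep]
    by_arm: Dict[str, List[KneeRecord]] = {}
    for r in records:
        by_arm.setdefault(r.arm, []).append(r)
    if len(by_arm) != 2 or any(len(v) < 2 for v in by_arm.values()):
        raise DataError("report needs two arms with at least two knees each")
    arms = sorted(by_arm, key=lambda a: a != "noyes")  # noyes first

    blocks: Dict[str, MeasureBlock] = {}
    for meas in ("pts", "wbl_percent", "mpta", "jlca"):
        pre = {a: _measured(by_arm[a], meas, "pre") for a in arms}
        post = {a: _measured(by_arm[a], meas, "post") for a in arms}
        blocks[meas] = MeasureBlock(
            measure=meas,
            pre_mean={a: float(pre[a].mean()) for a in arms},
            pre_sd={a: float(pre[a].std(ddof=1)) for a in arms},
            post_mean={a: float(post[a].mean()) for a in arms},
            post_sd={a: float(post[a].std(ddof=1)) for a in arms},
            p_between_pre=two_sample_t(pre[arms[0]], pre[arms[1]])[1],
            p_between_post=two_sample_t(post[arms[0]], post[arms[1]])[1],
            p_within={a: paired_t(pre[a], post[a])[1] for a in arms},
        )

    counts = {}
    for a in arms:
        labels = [classify_accuracy(v) for v in _measured(by_arm[a], "wbl_percent", "post")]
        counts[a] = {
            "under": labels.count("under"),
            "within": labels.count("within"),
            "over": labels.count("over"),
        }
    tab = [
        [counts[a]["within"], counts[a]["under"] + counts[a]["over"]] for a in arms
    ]
    chi2p = chi_square_2x2(tab)

    mpta_post = np.concatenate([_measured(by_arm[a], "mpta", "post") for a in arms])
    wbl_post = np.concatenate(
        [_measured(by_arm[a], "wbl_percent", "post") for a in arms]
    )
    slope, intercept, p = linreg_wbl_on_mpta(mpta_post, wbl_post)

    pa = _measured(by_arm[arms[0]], power_measure, "post")
    pb = _measured(by_arm[arms[1]], power_measure, "post")
    power = posthoc_power(len(pa), len(pb), abs(cohens_d(pa, pb)))

    return ComparisonReport(
        schema_version="1.0",
        n_per_arm={a: len(by_arm[a]) for a in arms},
        blocks=blocks,
        accuracy_counts=counts,
        chi2_within_band=chi2p,
        regression={"slope": slope, "intercept": intercept, "p": p},
        posthoc_power=power,
        match=match,
    )
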