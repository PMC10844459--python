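"""Cohort statistics: pairwise group contrasts and clinical correlations.

Each feature is compared between each pair of groups by a two-sided
independent two-sample t-test with pooled variance, with the effect
size summarized by Cohen's d on the pooled (n-1 weighted) standard
deviation.  Feature-score associations use Pearson's r for the
continuous clinical scales (MoCA, UHDRS functional and motor) and
Spearman's rho for the ordinal dysarthria score.  No multiple-testing
adjustment is applied by default — the analysis is exploratory and
favors sensitivity over strict type-I control — but Benjamini-Hochberg
correction can be switched on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GROUPS, VisitRecord, visits_to_frame

__all__ = [
    "GroupContrast",
    "cohens_d",
    "pairwise_group_table",
    "correlation_table",
    "sample_cohens_d",
    "significant_features",
    "CLINICAL_SCORES",
]

#: clinical score column -> correlation method
CLINICAL_SCORES = {
    "moca": "pearson",
    "uhdrs_functional": "pearson",
    "uhdrs_motor": "pearson",
    "dysarthria": "spearman",
}


@dataclass(frozen=True)
class GroupContrast:
    feature: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    d: float
    p: float


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation.

    ``d = (mean_a - mean_b) / s_p`` with
    ``s_p = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2))``.
    Antisymmetric under swapping the groups; NaN when the pooled SD is 0.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("cohens_d requires n >= 2 in each group")
    s_pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if s_pooled == 0:
        return float("nan")
    return (mean_a - mean_b) / s_pooled


def _contrast(feature: str, ga: str, gb: str, a: np.ndarray, b: np.ndarray) -> GroupContrast:
    mean_a, sd_a = float(np.mean(a)), float(np.std(a, ddof=1))
    mean_b, sd_b = float(np.mean(b)), float(np.std(b, ddof=1))
    d = cohens_d(mean_a, sd_a, len(a), mean_b, sd_b, len(b))
    t = sps.ttest_ind(a, b, equal_var=True)
    return GroupContrast(
        feature=feature, group_a=ga, group_b=gb,
        mean_a=mean_a, sd_a=sd_a, n_a=len(a),
        mean_b=mean_b, sd_b=sd_b, n_b=len(b),
        d=d, p=float(t.pvalue),
    )


def pairwise_group_table(
    visits: Sequence[VisitRecord],
    features: Sequence[str],
    groups: Sequence[str] = GROUPS,
    group_field: str = "group",
    fdr: bool = False,
) -> pd.DataFrame:
    """Pairwise group contrasts (t-test + Cohen's d) for each feature.

    ``group_field`` may name any categorical visit attribute (e.g.
    ``"dysarthria"`` to contrast dysarthria severity strata).  Groups
    with fewer than two non-missing observations yield a NaN row for
    that contrast; the run continues.
    """
    df = visits_to_frame(visits)
    rows = []
    for feature in features:
        if feature not in df.columns:
            raise KeyError(f"unknown feature {feature!r}")
        for ga, gb in itertools.combinations(groups, 2):
            a = df.loc[df[group_field].astype(str) == str(ga), feature].dropna().to_numpy()
            b = df.loc[df[group_field].astype(str) == str(gb), feature].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                rows.append(
                    {
                        "feature": feature, "group_a": ga, "group_b": gb,
                        "mean_a": np.nan, "sd_a": np.nan, "n_a": len(a),
                        "mean_b": np.nan, "sd_b": np.nan, "n_b": len(b),
                        "d": np.nan, "p": np.nan,
                    }
                )
                continue
            rows.append(_contrast(feature, str(ga), str(gb), a, b).__dict__)
    table = pd.DataFrame(rows)
    if fdr:
        mask = table["p"].notna()
        table.loc[mask, "p_adjusted"] = sps.false_discovery_control(
            table.loc[mask, "p"], method="bh"
        )
    return table


def correlation_table(
    visits: Sequence[VisitRecord],
    features: Sequence[str],
    scores: Sequence[str] = tuple(CLINICAL_SCORES),
) -> pd.DataFrame:
    """Feature-by-clinical-score correlations with two-sided p-values.

    Pearson for continuous scales, Spearman for the ordinal dysarthria
    score; pairwise-complete observations; constant features give NaN.
    """
    df = visits_to_frame(visits)
    rows = []
    for feature in features:
        for score in scores:
            method = CLINICAL_SCORES.get(score, "pearson")
            sub = df[[feature, score]].dropna()
            x, y = sub[feature].to_numpy(float), sub[score].to_numpy(float)
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                coef, p = np.nan, np.nan
            elif method == "spearman":
                res = sps.spearmanr(x, y)
                coef, p = float(res.statistic), float(res.pvalue)
            else:
                res = sps.pearsonr(x, y)
                coef, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "feature": feature, "clinical_score": score,
                    "coefficient": coef, "p": p, "method": method,
                    "n": len(x),
                }
            )
    return pd.DataFrame(rows)


def significant_features(
    visits: Sequence[VisitRecord],
    features: Sequence[str],
    alpha: float = 0.05,
    groups: Sequence[str] = GROUPS,
    group_field: str = "group",
) -> list[str]:
    """Features with at least one pairwise contrast below ``alpha``.

    This is the default feature-selection rule feeding the prediction
    models: a feature enters if any of its group contrasts in the
    analyzed cohort is nominally significant.
    """
    table = pairwise_group_table(visits, features, groups=groups, group_field=group_field)
    keep = (
        table.dropna(subset=["p"])
        .groupby("feature")["p"]
        .min()
        .pipe(lambda s: s[s < alpha])
        .index
    )
    return [f for f in features if f in set(keep)]


def sample_cohens_d(x: np.ndarray, y: np.ndarray, debias: bool = False) -> float:
    """Cohen's d from raw samples, optionally small-sample bias-corrected.

    The plain sample d overestimates |d| in small groups because the
    pooled SD sits in the denominator.  With ``debias=True`` the Hedges
    correction ``J(nu) = 1 - 3 / (4 nu - 1)`` is applied, with ``nu``
    the Satterthwaite effective degrees of freedom of the pooled
    variance — the pooled df under-corrects when group variances differ
    strongly.  Used by simulation-recovery studies where an unbiased
    estimate is compared against a known target.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n_a, n_b = len(x), len(y)
    d = cohens_d(
        float(np.mean(x)), float(np.std(x, ddof=1)), n_a,
        float(np.mean(y)), float(np.std(y, ddof=1)), n_b,
    )
    if not debias:
        return d
    va, vb = np.var(x, ddof=1), np.var(y, ddof=1)
    num = ((n_a - 1) * va + (n_b - 1) * vb) ** 2
    den = ((n_a - 1) * va) ** 2 / (n_a - 1) + ((n_b - 1) * vb) ** 2 / (n_b - 1)
    nu = num / den if den > 0 else n_a + n_b - 2
    return d * (1.0 - 3.0 / (4.0 * nu - 1.0))
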