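"""Group-level statistics: one-way ANOVA with eta-squared, Tukey-Kramer
HSD, the cubic lap-trend fit, and subjective questionnaire scores.

The ANOVA observation unit for the tier comparison is the participant x
pathway mean (seven turn means per participant), which with 15 drivers
in 3 tiers yields df = (2, 102).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .synthetic import NEGATIVE_EMOTIONS, POSITIVE_EMOTIONS

#: default circumplex placement of the questionnaire emotions
AROUSAL_MAP = {
    "high": ("excited", "tense", "angry", "frustrated"),
    "low": ("relaxed", "calm", "tired", "bored", "depressed"),
}


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ss_between: float
    ss_within: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA with eta-squared.

    ``groups`` maps group name -> 1-D observations.  F = MSB/MSW and
    eta^2 = SSB/SST, the fraction of total variance between groups.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for k, a in arrays.items():
        if len(a) == 0:
            raise ValueError(f"group {k!r} has no observations")
    all_vals = np.concatenate(list(arrays.values()))
    n = len(all_vals)
    k = len(arrays)
    if n - k < 1:
        raise ValueError("not enough observations for within-group variance")
    grand = all_vals.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        F = np.inf if ssb > 0 else 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
    p = float(sst.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
    sst_total = ssb + ssw
    eta2 = ssb / sst_total if sst_total > 0 else 0.0
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p,
                       eta_squared=float(eta2), ss_between=float(ssb),
                       ss_within=float(ssw))


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise comparisons by the studentized-range (Tukey) test.

    Uses the Tukey-Kramer standard error for unequal group sizes:
    SE_q = sqrt(MSW/2 * (1/n_i + 1/n_j)); q = |diff|/SE_q; the adjusted
    p is the studentized-range tail with k groups and the ANOVA's
    within-group df.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    anova = one_way_anova(arrays)
    msw = anova.ss_within / anova.df_within
    k = len(arrays)
    rows = []
    for g1, g2 in combinations(arrays, 2):
        a, b = arrays[g1], arrays[g2]
        diff = a.mean() - b.mean()
        se = np.sqrt(msw / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(sst.studentized_range.sf(q, k, anova.df_within))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff,
                     "se": se, "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    coefficients: np.ndarray     # highest degree first
    r_squared: float
    F: float
    p: float
    degree: int
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def fit_polynomial_trend(x, y, degree: int = 3) -> TrendFit:
    """Least-squares polynomial fit with an overall-regression F test.

    R^2 = 1 - SS_res/SS_tot; the p-value tests all non-intercept
    coefficients jointly against the intercept-only model with
    df = (degree, n - degree - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    resid = y - fitted
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model, df_res = degree, len(x) - degree - 1
    if ss_res == 0:
        F, p = np.inf, 0.0
    elif ss_tot == ss_res:
        F, p = 0.0, 1.0
    else:
        F = ((ss_tot - ss_res) / df_model) / (ss_res / df_res)
        p = float(sst.f.sf(F, df_model, df_res))
    return TrendFit(coefficients=coeffs, r_squared=float(r2), F=float(F),
                    p=p, degree=degree, residuals=resid)


def subjective_scores(questionnaire: pd.DataFrame,
                      weights: tuple[float, float] = (0.5, 0.5),
                      arousal_map: dict | None = None) -> pd.DataFrame:
    """Feel index, valence and arousal per participant.

    feel = w1*driving_experience + w2*car_responsive_feel;
    valence = mean(positive emotions) - mean(negative emotions);
    arousal = mean(high-arousal items) - mean(low-arousal items).
    """
    amap = AROUSAL_MAP if arousal_map is None else arousal_map
    needed = list(POSITIVE_EMOTIONS) + list(NEGATIVE_EMOTIONS) + [
        "driving_experience", "car_responsive_feel"]
    for col in needed:
        if col not in questionnaire.columns:
            raise ValueError(f"questionnaire missing column {col!r}")
    vals = questionnaire[needed]
    if ((vals < 0) | (vals > 10)).to_numpy().any():
        raise ValueError("questionnaire ratings must lie in [0, 10]")
    w1, w2 = weights
    out = pd.DataFrame(index=questionnaire.index)
    out["feel_index"] = (w1 * questionnaire["driving_experience"]
                         + w2 * questionnaire["car_responsive_feel"])
    out["valence"] = (questionnaire[list(POSITIVE_EMOTIONS)].mean(axis=1)
                      - questionnaire[list(NEGATIVE_EMOTIONS)].mean(axis=1))
    out["arousal"] = (questionnaire[list(amap["high"])].mean(axis=1)
                      - questionnaire[list(amap["low"])].mean(axis=1))
    return out


def correlate_subjective_objective(subjective: pd.DataFrame,
                                   objective: pd.DataFrame,
                                   method: str = "spearman") -> pd.DataFrame:
    """Correlate each subjective score with each objective column.

    Long format: subjective, objective, rho, p, n.  Pairs with a
    constant column get rho = NaN (correlation undefined).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    joined = subjective.join(objective, how="inner")
    if len(joined) < 3:
        raise ValueError("need at least 3 participants for correlation")
    corr = sst.spearmanr if method == "spearman" else sst.pearsonr
    rows = []
    for s in subjective.columns:
        for o in objective.columns:
            x = joined[s].to_numpy(dtype=float)
            y = joined[o].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho, p = np.nan, np.nan
            else:
                res = corr(x, y)
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"subjective": s, "objective": o, "rho": rho,
                         "p": p, "n": len(joined)})
    return pd.DataFrame(rows)
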