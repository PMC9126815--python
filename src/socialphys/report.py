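"""Statistical battery and run report.

Implements the study's testing conventions: normality is screened with
Shapiro–Wilk (α = 0.05) and, when rejected, the parametric test is
replaced by its non-parametric counterpart (paired t → Wilcoxon
signed-rank, one-sample t → signed-rank against the chance level).
F–I curves are compared with a mixed repeated-measures ANOVA (between
factor group, within factor current step), Greenhouse–Geisser corrected
when sphericity is rejected.  An optional MAD screen flags (never
removes) candidate outliers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    """One statistical test with its normality-gate provenance."""

    name: str
    statistic: float
    p: float
    n: int
    df: float | None = None
    normality_used: bool = True
    fallback_test: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


def _shapiro_ok(values: np.ndarray, alpha: float = 0.05) -> bool:
    values = np.asarray(values, float)
    if np.ptp(values) == 0:
        return True  # constant data: parametric branch handles it
    return stats.shapiro(values).pvalue >= alpha


def preference_tests(time_social: np.ndarray, time_object: np.ndarray,
                     indices: np.ndarray | None = None,
                     chance: float = 0.5,
                     normality_alpha: float = 0.05) -> dict[str, TestResult]:
    """Paired social-vs-object comparison plus index-vs-chance test.

    The paired test runs on the per-animal time differences; the
    one-sample test compares preference indices to the 0.5 chance
    level.  Shapiro–Wilk on the tested variable decides between the
    parametric test and its rank-based fallback.
    """
    ts = np.asarray(time_social, float)
    to = np.asarray(time_object, float)
    if ts.size != to.size:
        raise ValueError("paired samples must have equal length")
    if ts.size < 3:
        raise ValueError("need at least 3 paired observations")
    if indices is None:
        indices = ts / (ts + to)
    indices = np.asarray(indices, float)

    diffs = ts - to
    out = {}
    if _shapiro_ok(diffs, normality_alpha):
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            res = TestResult("paired t-test", 0.0, 1.0, ts.size,
                             df=ts.size - 1)
        else:
            r = stats.ttest_rel(ts, to)
            res = TestResult("paired t-test", float(r.statistic),
                             float(r.pvalue), ts.size, df=float(r.df))
    else:
        r = stats.wilcoxon(ts, to)
        res = TestResult("paired t-test", float(r.statistic), float(r.pvalue),
                         ts.size, normality_used=False,
                         fallback_test="Wilcoxon signed-rank")
    out["paired_social_vs_object"] = res

    dev = indices - chance
    if _shapiro_ok(dev, normality_alpha):
        if np.ptp(dev) == 0 and dev[0] == 0:
            res = TestResult("one-sample t-test vs 0.5", 0.0, 1.0,
                             indices.size, df=indices.size - 1)
        else:
            r = stats.ttest_1samp(indices, chance)
            res = TestResult("one-sample t-test vs 0.5", float(r.statistic),
                             float(r.pvalue), indices.size, df=float(r.df))
    else:
        r = stats.wilcoxon(dev)
        res = TestResult("one-sample t-test vs 0.5", float(r.statistic),
                         float(r.pvalue), indices.size, normality_used=False,
                         fallback_test="Wilcoxon signed-rank")
    out["index_vs_chance"] = res
    return out


def fi_comparison(fi_long: pd.DataFrame, dv: str = "nAP", within: str = "step_pA",
                  subject: str = "cell", between: str = "group") -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on the F–I table.

    ``fi_long`` is long format (cell, step_pA, nAP, group).  Cells with
    missing steps are excluded listwise (and reported via a warning).
    Returns the pingouin ANOVA table (group main effect, step main
    effect, interaction); sphericity handling (Greenhouse–Geisser) is
    applied by the backend when violated.
    """
    import pingouin as pg

    if fi_long[between].nunique() < 2:
        raise ValueError("need at least two groups")
    n_steps = fi_long[within].nunique()
    counts = fi_long.groupby(subject)[within].nunique()
    complete = counts.index[counts == n_steps]
    if len(complete) < len(counts):
        dropped = sorted(set(counts.index) - set(complete))
        warnings.warn(f"excluding cells with missing steps: {dropped}")
    data = fi_long[fi_long[subject].isin(complete)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=data, dv=dv, within=within,
                             subject=subject, between=between, correction=True)
    # one headline p per effect: Greenhouse–Geisser when sphericity rejected
    gg = aov.get("p_GG_corr")
    sph = aov.get("sphericity")
    p = aov["p_unc"].copy()
    if gg is not None and sph is not None:
        use_gg = (sph == False) & gg.notna()  # noqa: E712 (pandas mask)
        p[use_gg] = gg[use_gg]
    aov = aov.assign(p=p)
    return aov


def outlier_screen(values: np.ndarray, method: str = "mad",
                   cutoff: float = 3.5) -> np.ndarray:
    """Flag values beyond ``cutoff`` robust deviations from the median.

    A flag-only stand-in for automated outlier removal: values farther
    than ``cutoff`` scaled median-absolute-deviations from the median
    are marked True.  Nothing is removed; with zero MAD no flags are
    raised and a warning is issued.
    """
    values = np.asarray(values, float)
    if method == "none":
        return np.zeros(values.size, bool)
    if method != "mad":
        raise ValueError(f"unknown method {method!r}")
    if values.size < 4:
        raise ValueError("outlier screen needs at least 4 values")
    med = np.median(values)
    mad = np.median(np.abs(values - med)) * 1.4826  # ≈ SD for normal data
    if mad == 0:
        warnings.warn("zero MAD: no outliers flagged")
        return np.zeros(values.size, bool)
    return np.abs(values - med) / mad > cutoff


# -- run report -------------------------------------------------------------


def build_report(panels: dict[str, object]) -> str:
    """Serialize a dict of analysis panels to deterministic JSON.

    Dataclasses, numpy scalars/arrays and DataFrames are converted to
    plain JSON types; keys are sorted so regeneration from the same
    inputs is byte-identical.
    """
    return json.dumps(_jsonable(panels), indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TestResult):
        return _jsonable(asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, (np.ndarray,)):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
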