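"""Normality-gated paired comparisons with dual-criterion positivity.

Each imaging metric is compared between the larger and smaller lesion twice:
on the raw per-lesion values, and on the values after subtracting each
lesion's mirrored contralateral control (to absorb spatial heterogeneity).
The Shapiro-Wilk test on the pair differences gates the test choice
(paired t when SW p >= 0.05, Wilcoxon signed-rank otherwise), effect sizes
are Cohen's d (t) or r = |Z|/sqrt(n) (Wilcoxon), and a finding is positive
only when BOTH approaches survive the Bonferroni family threshold
alpha / m, with m = metrics-per-family x 2 approaches.  Dual-positive
metrics are re-examined with a linear mixed-effects model (random intercept
per subject; fixed effects: lesion group, volume, tSNR, number of
intersected resting-state networks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: Metric families and their members; family size m = 2 * len(metrics).
FAMILIES = {
    "activity": ("alff", "falff", "reho"),
    "connectivity": ("mean_fc", "n_sig", "mean_dist"),
    "topology": ("degree", "betweenness", "closeness", "clustering"),
}

SEED_PAIRS = (("larger", "larger_control"), ("smaller", "smaller_control"))


@dataclass
class PairedComparison:
    metric: str
    test_used: str               # "paired-t" | "wilcoxon"
    statistic: float
    p_two_sided: float
    effect_size: float
    effect_size_type: str        # "cohens_d" | "wilcoxon_r"
    n_pairs: int
    shapiro_p: float = float("nan")


class BonferroniThreshold(NamedTuple):
    exact: float
    rounded: float


@dataclass
class DualCriterionResult:
    raw: PairedComparison
    control_subtracted: PairedComparison
    family_size: int
    threshold: float
    positive: bool


@dataclass
class LmmFit:
    coefficients: dict
    p_values: dict
    random_intercept_var: float
    converged: bool
    singular: bool = False
    method: str = "reml"


def normality_gate(differences, alpha: float = 0.05) -> tuple[str, float]:
    """Choose the paired test from Shapiro-Wilk on the differences.

    Returns ``(test_name, shapiro_p)``; identical differences trigger a
    degeneracy warning and the Wilcoxon branch.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("normality gate needs at least 3 differences")
    if np.ptp(d) == 0:
        warnings.warn("all differences identical; Shapiro-Wilk undefined, using Wilcoxon",
                      stacklevel=2)
        return "wilcoxon", float("nan")
    sw_p = float(stats.shapiro(d).pvalue)
    return ("paired-t" if sw_p >= alpha else "wilcoxon"), sw_p


def _wilcoxon_z_r(d: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon signed-rank statistic, two-sided p and r = |Z|/sqrt(n).

    Normal approximation with continuity correction for n >= 10, exact
    distribution below; |Z| is recovered from the two-sided p so both modes
    share one effect-size scale.
    """
    n = d.size
    method = "exact" if n < 10 else "approx"
    try:
        res = stats.wilcoxon(d, correction=True, method=method)
    except ValueError:
        res = stats.wilcoxon(d, correction=True, method="approx")
    p = float(res.pvalue)
    z = float(stats.norm.isf(min(max(p / 2.0, 1e-300), 0.5)))
    z = max(z, 0.0)
    return float(res.statistic), p, z / np.sqrt(n)


def paired_compare(x, y, metric: str = "", alpha: float = 0.05) -> PairedComparison:
    """Normality-gated paired comparison of x against y (differences x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < x.size:
        warnings.warn(f"{metric or 'comparison'}: dropped {int(x.size - keep.sum())} "
                      "pair(s) with missing values", stacklevel=2)
    d = x[keep] - y[keep]
    n = d.size
    if n < 3:
        raise ValueError("paired comparison needs at least 3 complete pairs")
    if np.ptp(d) == 0:
        if d[0] == 0:  # x == y exactly: no effect, degenerate but well-defined
            return PairedComparison(metric, "wilcoxon", 0.0, 1.0, 0.0, "wilcoxon_r", n)
        raise ValueError("differences have zero variance (constant nonzero shift)")
    test, sw_p = normality_gate(d, alpha=alpha)
    if test == "paired-t":
        res = stats.ttest_1samp(d, 0.0)
        d_eff = float(d.mean() / d.std(ddof=1))
        return PairedComparison(metric, "paired-t", float(res.statistic),
                                float(res.pvalue), d_eff, "cohens_d", n, sw_p)
    stat, p, r = _wilcoxon_z_r(d)
    return PairedComparison(metric, "wilcoxon", stat, p, r, "wilcoxon_r", n, sw_p)


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Family threshold alpha/m, with the 3-decimal form used in reporting."""
    if m < 1:
        raise ValueError("family size m must be at least 1")
    exact = alpha / m
    return BonferroniThreshold(exact, round(exact, 3))


def dual_criterion(raw: PairedComparison, ctrl_sub: PairedComparison,
                   alpha: float = 0.05, m: int = 6) -> DualCriterionResult:
    """Positive only when both the raw and control-subtracted p beat alpha/m."""
    if raw.metric != ctrl_sub.metric:
        raise ValueError("dual criterion requires comparisons of the same metric")
    thr = bonferroni_threshold(alpha, m).exact
    positive = (raw.p_two_sided < thr) and (ctrl_sub.p_two_sided < thr)
    return DualCriterionResult(raw, ctrl_sub, m, thr, positive)


def fit_lmm(long_table: pd.DataFrame, value_col: str = "value", group_col: str = "group",
            subject_col: str = "subject",
            covariates=("volume", "tsnr", "n_networks"), reml: bool = True,
            standardize: bool = True) -> LmmFit:
    """Random-intercept linear mixed model: value ~ group + covariates.

    REML with Wald p-values; a singular random-effect fit is flagged and
    refitted by plain ML.  With ``standardize=True`` the covariates (not the
    group indicator) are z-scored, so their coefficients are per-SD; this
    leaves the group coefficient and all p-values unchanged while keeping
    the optimizer well conditioned across covariate units.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    needed = [subject_col, value_col, group_col, *covariates]
    missing = [c for c in needed if c not in long_table.columns]
    if missing:
        raise ValueError(f"long table missing columns {missing}")
    df = long_table.dropna(subset=needed).copy()
    if df.groupby(subject_col).size().min() < 2:
        raise ValueError("need at least 2 rows per subject for a random intercept")
    if standardize:
        for c in covariates:
            sd = df[c].std(ddof=1)
            if sd > 0:
                df[c] = (df[c] - df[c].mean()) / sd
    exog = sm.add_constant(df[[group_col, *covariates]].astype(float))
    rank = np.linalg.matrix_rank(exog.to_numpy())
    singular_design = rank < exog.shape[1]
    if singular_design:
        warnings.warn("collinear fixed-effect design; coefficients not identified",
                      stacklevel=2)
    model = sm.MixedLM(df[value_col].astype(float), exog, groups=df[subject_col])
    method = "reml" if reml else "ml"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False)
            method = "ml"
    converged = bool(getattr(fit, "converged", True))
    singular = singular_design or any("singular" in str(w.message).lower() for w in caught)
    if not converged and reml:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            refit = model.fit(reml=False)
        if getattr(refit, "converged", False):
            fit, converged, method = refit, True, "ml"
    return LmmFit(
        coefficients={k: float(v) for k, v in fit.params.items() if k != "Group Var"},
        p_values={k: float(v) for k, v in fit.pvalues.items() if k != "Group Var"},
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        converged=converged, singular=singular, method=method,
    )


@dataclass
class CohortStatsReport:
    """Dual-criterion verdicts and LMM adjustments per metric family."""

    alpha: float
    family_sizes: dict
    results: dict                # family -> metric -> DualCriterionResult
    lmm: dict                    # metric -> {"raw": LmmFit, "control_subtracted": LmmFit}
    n_subjects: int
    notes: list = field(default_factory=list)

    def positives(self) -> list:
        return [(fam, met) for fam, d in self.results.items()
                for met, r in d.items() if r is not None and r.positive]

    def to_dict(self) -> dict:
        def comp(c):
            return None if c is None else {
                "test": c.test_used, "statistic": c.statistic, "p": c.p_two_sided,
                "effect_size": c.effect_size, "effect_size_type": c.effect_size_type,
                "n_pairs": c.n_pairs,
            }
        out = {"alpha": self.alpha, "family_sizes": self.family_sizes,
               "n_subjects": self.n_subjects, "notes": list(self.notes), "families": {}}
        for fam, d in self.results.items():
            out["families"][fam] = {}
            for met, r in d.items():
                if r is None:
                    out["families"][fam][met] = None
                    continue
                out["families"][fam][met] = {
                    "raw": comp(r.raw), "control_subtracted": comp(r.control_subtracted),
                    "threshold": r.threshold, "family_size": r.family_size,
                    "positive": r.positive,
                }
        out["lmm"] = {
            met: {kind: {"coefficients": f.coefficients, "p_values": f.p_values,
                         "random_intercept_var": f.random_intercept_var,
                         "converged": f.converged, "singular": f.singular,
                         "method": f.method}
                  for kind, f in kinds.items()}
            for met, kinds in self.lmm.items()
        }
        return out


def _pivot(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = df[df["metric"] == metric]
    return sub.pivot_table(index="subject", columns="seed_type", values="value",
                           aggfunc="first")


def run_cohort_stats(long_df: pd.DataFrame, alpha: float = 0.05,
                     fit_lmms=True) -> CohortStatsReport:
    """Run the full paired workflow over a long-format cohort metric table.

    Expected columns: subject, seed_type (larger / smaller / larger_control /
    smaller_control), family, metric, value, volume, tsnr, n_networks.
    Family sizes are fixed by the metric families (3 x 2 = 6 for activity and
    connectivity, 4 x 2 = 8 for topology).  Missing pairs are dropped with a
    note; a metric without enough complete pairs yields a None entry.
    ``fit_lmms`` may be True (all dual-positive metrics), False, or an
    iterable of metric names to restrict the mixed-model adjustment to.
    """
    lmm_wanted = (lambda m: bool(fit_lmms)) if isinstance(fit_lmms, bool) \
        else (lambda m, _s=frozenset(fit_lmms): m in _s)
    required = {"subject", "seed_type", "family", "metric", "value"}
    if not required.issubset(long_df.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    n_subjects = int(long_df["subject"].nunique())
    results: dict = {}
    lmm: dict = {}
    notes: list = []
    family_sizes = {fam: 2 * len(mets) for fam, mets in FAMILIES.items()}
    present = set(long_df["family"].unique())

    for fam, metrics in FAMILIES.items():
        if fam not in present:
            continue
        m = family_sizes[fam]
        results[fam] = {}
        for metric in metrics:
            piv = _pivot(long_df, metric)
            if piv.empty or not {"larger", "smaller"}.issubset(piv.columns):
                results[fam][metric] = None
                notes.append(f"{fam}/{metric}: no data")
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    raw = paired_compare(piv["larger"], piv["smaller"], metric=metric)
                    ctrl = paired_compare(piv["larger"] - piv.get("larger_control"),
                                          piv["smaller"] - piv.get("smaller_control"),
                                          metric=metric)
            except (ValueError, KeyError, TypeError) as err:
                results[fam][metric] = None
                notes.append(f"{fam}/{metric}: comparison unavailable ({err})")
                continue
            res = dual_criterion(raw, ctrl, alpha=alpha, m=m)
            results[fam][metric] = res
            if res.positive and lmm_wanted(metric):
                lmm[metric] = _lmm_pair(long_df, metric)
    return CohortStatsReport(alpha=alpha, family_sizes=family_sizes, results=results,
                             lmm=lmm, n_subjects=n_subjects, notes=notes)


def _lmm_pair(long_df: pd.DataFrame, metric: str) -> dict:
    """Raw and control-subtracted LMMs for one metric."""
    sub = long_df[long_df["metric"] == metric]
    rows = []
    for _, grp in sub.groupby("subject"):
        by_seed = grp.set_index("seed_type")
        for tumor, control in SEED_PAIRS:
            if tumor not in by_seed.index:
                continue
            trow = by_seed.loc[tumor]
            rows.append({
                "subject": trow.get("subject", grp["subject"].iloc[0]),
                "group": 1.0 if tumor == "larger" else 0.0,
                "value": trow["value"],
                "value_ctrl_sub": trow["value"] - by_seed.loc[control, "value"]
                if control in by_seed.index else np.nan,
                "volume": trow.get("volume", np.nan),
                "tsnr": trow.get("tsnr", np.nan),
                "n_networks": trow.get("n_networks", np.nan),
            })
    df = pd.DataFrame(rows)
    out: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out["raw"] = fit_lmm(df)
        except (ValueError, KeyError) as err:
            warnings.warn(f"raw LMM for {metric} unavailable: {err}")
        try:
            out["control_subtracted"] = fit_lmm(df.assign(value=df["value_ctrl_sub"]))
        except (ValueError, KeyError) as err:
            warnings.warn(f"control-subtracted LMM for {metric} unavailable: {err}")
    return out
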