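"""Efficiency-corrected relative quantification of qPCR data (2^-ddCq).

Workflow
--------
1. Each measured quantification cycle Cq is rescaled by its primer's
   amplification efficiency E (1 = perfect doubling per cycle):

       Cq_E = Cq * log2(1 + E)

   so that one corrected cycle always corresponds to a doubling.
2. Target-gene Cq_E values are normalised against the geometric mean of
   two reference genes.  On the expression (2^-Cq) scale the geometric
   mean corresponds exactly to the arithmetic mean of corrected Cq, which
   is what is subtracted:  dCq = Cq_E(target) - mean(Cq_E(ref1), Cq_E(ref2)).
3. ddCq = mean dCq(treatment) - mean dCq(control); the relative fold
   change is 2^-ddCq and log2FC = -ddCq.  Standard error propagation
   combines the two group SEs: SE(ddCq) = sqrt(SE_t^2 + SE_c^2).
4. Group means of dCq are compared by a two-tailed Student t test
   (pooled variance; Welch available behind a flag) after logging
   Shapiro-Wilk normality and Levene homoscedasticity checks — the gates
   warn but do not switch tests.  FDR across the comparisons reported
   together is controlled with Storey q-values.

The module also hosts the morphometric group tests (Kruskal-Wallis /
Wilcoxon rank sum) used on body weight and length data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .errors import ConfigurationError, UndefinedValueError
from .locus_stats import adjust_bh

logger = logging.getLogger(__name__)

_REQUIRED_COLS = ["sample", "group", "gene", "cq", "efficiency"]


@dataclass
class QpcrExperiment:
    """Long-format Cq measurements with per-gene efficiencies.

    ``measurements`` columns: sample, group, gene, cq, efficiency.
    Exactly two reference genes are required; every sample must carry a
    Cq for both before normalisation.
    """

    measurements: pd.DataFrame
    reference_genes: tuple[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLS if c not in self.measurements.columns]
        if missing:
            raise ConfigurationError(f"measurements lack column(s): {', '.join(missing)}")
        if len(self.reference_genes) != 2:
            raise ConfigurationError("exactly 2 reference genes are required")
        self.reference_genes = tuple(self.reference_genes)
        eff = self.measurements["efficiency"].to_numpy(dtype=float)
        if np.any(~((eff > 0) & (eff <= 1))):
            raise ConfigurationError("efficiency must lie in (0, 1]")
        genes = set(self.measurements["gene"])
        for rg in self.reference_genes:
            if rg not in genes:
                raise ConfigurationError(f"reference gene {rg!r} absent from data")

    @property
    def target_genes(self) -> list[str]:
        refs = set(self.reference_genes)
        return [g for g in pd.unique(self.measurements["gene"]) if g not in refs]

    @classmethod
    def from_csv(cls, path, reference_genes) -> "QpcrExperiment":
        return cls(pd.read_csv(path), tuple(reference_genes))

    def to_csv(self, path) -> None:
        self.measurements.to_csv(path, index=False, lineterminator="\n")


@dataclass
class ExpressionSummary:
    gene: str
    treatment: str
    control: str
    mean_dcq_treatment: float
    mean_dcq_control: float
    se_treatment: float
    se_control: float
    ddcq: float
    log2_fold_change: float
    fold_change: float
    ci_low: float
    ci_high: float
    confidence: float
    t: float = float("nan")
    df: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")


def efficiency_correct(cq, efficiency) -> np.ndarray | float:
    """Corrected quantification cycle Cq_E = Cq * log2(1 + E)."""
    e = np.asarray(efficiency, dtype=float)
    if np.any(~((e > 0) & (e <= 1))):
        raise ConfigurationError("efficiency must lie in (0, 1]")
    out = np.asarray(cq, dtype=float) * np.log2(1.0 + e)
    return float(out) if out.ndim == 0 else out


def delta_cq(experiment: QpcrExperiment) -> pd.DataFrame:
    """Per-sample per-target dCq after efficiency correction.

    dCq = Cq_E(target) - mean of the two reference genes' Cq_E (the
    arithmetic mean of corrected Cq equals the geometric mean on the
    expression scale).  Returns columns sample, group, gene, dcq.
    """
    df = experiment.measurements.copy()
    df["cq_e"] = efficiency_correct(df["cq"].to_numpy(), df["efficiency"].to_numpy())
    refs = df[df["gene"].isin(experiment.reference_genes)]
    ref_mean = refs.groupby("sample").agg(
        ref_cq_e=("cq_e", "mean"), n_ref=("gene", "nunique")
    )
    targets = df[~df["gene"].isin(experiment.reference_genes)].copy()
    merged = targets.merge(ref_mean, left_on="sample", right_index=True, how="left")
    bad = merged[merged["ref_cq_e"].isna() | (merged["n_ref"] < 2)]
    if not bad.empty:
        r = bad.iloc[0]
        raise UndefinedValueError(
            f"sample {r['sample']!r} lacks both reference genes for target {r['gene']!r}"
        )
    merged["dcq"] = merged["cq_e"] - merged["ref_cq_e"]
    return merged[["sample", "group", "gene", "dcq"]].reset_index(drop=True)


def fold_change(
    dcq_treatment, dcq_control, *, gene: str = "", treatment: str = "treatment",
    control: str = "control", confidence: float = 0.95
) -> ExpressionSummary:
    """2^-ddCq fold change with propagated error and a normal-quantile CI.

    ddCq = mean(treatment dCq) - mean(control dCq); log2FC = -ddCq;
    SE(ddCq) = sqrt(SE_t^2 + SE_c^2); the CI on log2FC is
    -ddCq -/+ t_(df) * SE with df = n_t + n_c - 2.  A Student-t rather
    than a normal quantile is used because the SE is estimated from few
    replicates (typically 4 per group); with a normal quantile the
    nominal 95% interval would cover only ~90% at that size.
    Requires >= 2 values per group.
    """
    t_vals = np.asarray(list(dcq_treatment), dtype=float)
    c_vals = np.asarray(list(dcq_control), dtype=float)
    if len(t_vals) < 2 or len(c_vals) < 2:
        raise ConfigurationError("fold_change requires >= 2 dCq values per group")
    if not 0 < confidence < 1:
        raise ConfigurationError("confidence must lie in (0, 1)")
    se_t = t_vals.std(ddof=1) / math.sqrt(len(t_vals))
    se_c = c_vals.std(ddof=1) / math.sqrt(len(c_vals))
    ddcq = float(t_vals.mean() - c_vals.mean())
    se = math.sqrt(se_t**2 + se_c**2)
    z = stats.t.ppf(0.5 + confidence / 2, df=len(t_vals) + len(c_vals) - 2)
    log2fc = -ddcq
    return ExpressionSummary(
        gene=gene,
        treatment=treatment,
        control=control,
        mean_dcq_treatment=float(t_vals.mean()),
        mean_dcq_control=float(c_vals.mean()),
        se_treatment=float(se_t),
        se_control=float(se_c),
        ddcq=ddcq,
        log2_fold_change=log2fc,
        fold_change=float(2.0**log2fc),
        ci_low=log2fc - z * se,
        ci_high=log2fc + z * se,
        confidence=confidence,
    )


def _student_t(a: np.ndarray, b: np.ndarray, pooled: bool = True):
    if pooled and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        # infinite t; p -> 0
        return math.inf if a.mean() > b.mean() else -math.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = len(a) + len(b) - 2 if pooled else res.df
    return float(res.statistic), float(df), float(res.pvalue)


def expression_tests(
    dcq_by_group: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    *,
    confidence: float = 0.95,
    welch: bool = False,
    pi0_method: str = "smoother",
) -> list[ExpressionSummary]:
    """Per-gene treatment-vs-control tests with Storey q-values.

    ``dcq_by_group`` is the frame produced by :func:`delta_cq`.  For each
    gene and each (treatment, control) pair, group means of dCq are
    compared by a two-tailed Student t (pooled variance unless
    ``welch=True``).  Shapiro-Wilk and Levene checks are evaluated per
    comparison and logged (never auto-switching the test).  q-values are
    estimated jointly across every comparison in the call, mirroring how
    batches of two-group comparisons are reported together.
    """
    summaries: list[ExpressionSummary] = []
    for treatment, control in comparisons:
        for gene in pd.unique(dcq_by_group["gene"]):
            sub = dcq_by_group[dcq_by_group["gene"] == gene]
            t_vals = sub.loc[sub["group"] == treatment, "dcq"].to_numpy(dtype=float)
            c_vals = sub.loc[sub["group"] == control, "dcq"].to_numpy(dtype=float)
            if len(t_vals) == 0 or len(c_vals) == 0:
                raise ConfigurationError(
                    f"empty group in comparison {treatment} vs {control} for gene {gene}"
                )
            summ = fold_change(
                t_vals, c_vals, gene=gene, treatment=treatment, control=control,
                confidence=confidence,
            )
            if min(len(t_vals), len(c_vals)) >= 3:
                for label, vals in (("treatment", t_vals), ("control", c_vals)):
                    if np.ptp(vals) > 0:
                        w, p_sw = stats.shapiro(vals)
                        if p_sw < 0.05:
                            logger.warning(
                                "%s %s vs %s: Shapiro-Wilk p = %.3g in %s group",
                                gene, treatment, control, p_sw, label)
                if np.ptp(t_vals) > 0 or np.ptp(c_vals) > 0:
                    _, p_lev = stats.levene(t_vals, c_vals, center="median")
                    if p_lev < 0.05:
                        logger.warning("%s %s vs %s: Levene p = %.3g",
                                       gene, treatment, control, p_lev)
            # compare control-minus-treatment dCq so that t is oriented on
            # the expression scale (positive t = upregulation), matching how
            # such statistics are conventionally reported
            summ.t, summ.df, summ.p = _student_t(c_vals, t_vals, pooled=not welch)
            summaries.append(summ)
    qs = storey_qvalues([s.p for s in summaries], pi0_method=pi0_method)
    for s, q in zip(summaries, qs):
        s.q = float(q)
    return summaries


def summaries_to_frame(summaries: list[ExpressionSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def estimate_pi0(p_values, method: str = "smoother") -> float:
    """Proportion of true nulls, by the smoother estimator.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.95; a cubic smoothing spline through the
    pi0(lambda) points is evaluated at the largest lambda and clipped to
    (0, 1].  ``method="fixed"`` returns 1 (reducing q-values to BH).
    """
    p = np.asarray(list(p_values), dtype=float)
    if method == "fixed":
        return 1.0
    if method != "smoother":
        raise ConfigurationError(f"unknown pi0 method {method!r}")
    m = p.size
    if m < 2:
        logger.info("fewer than 2 p-values; pi0 fixed at 1")
        return 1.0
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    if pi0 > 1 or pi0 <= 0:
        logger.info("pi0 smoother outside (0, 1] (%.3f); clipped", pi0)
    return min(1.0, max(pi0, 1.0 / m))


def storey_qvalues(p_values, pi0_method: str = "smoother") -> np.ndarray:
    """Storey q-values: q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).

    With pi0 forced to 1 (``pi0_method="fixed"``) the result equals the
    Benjamini-Hochberg adjustment.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    pi0 = estimate_pi0(p, method=pi0_method)
    return np.minimum(pi0 * adjust_bh(p), 1.0)


def morphometric_tests(values_by_group: dict[str, list[float]], design: str):
    """Group tests on morphometric traits (weight, length).

    ``design="multi_group"`` runs the Kruskal-Wallis rank sum test
    (tie-corrected chi-square); ``design="two_group"`` the two-sided
    Wilcoxon rank sum test, reporting the W statistic of the first group
    (the number of pairs it wins).  Returns (statistic, p).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("all groups must be non-empty")
    if design == "multi_group":
        if len(groups) < 2:
            raise ConfigurationError("multi_group requires >= 2 groups")
        if np.ptp(np.concatenate(groups)) == 0:
            return 0.0, 1.0
        stat, p = stats.kruskal(*groups)
        return float(stat), float(p)
    if design == "two_group":
        if len(groups) != 2:
            raise ConfigurationError("two_group requires exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ConfigurationError(f"unknown design {design!r}")
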