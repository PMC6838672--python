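"""Normalization and differential testing of kinase-activation readouts.

Ratios to the heavy internal standard are first normalized to a reference
(control) condition, log2-transformed, technical replicates averaged
within each biological replicate, and condition differences tested with a
per-peptide fixed-effects comparison of biological-replicate means — for
two conditions, an equal-variance two-sample t-test. With technical
replicates collapsed, this matches the balanced-design linear
mixed-effects analysis while staying deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("peptide", "condition", "bio_rep", "tech_rep", "ratio")


class DifferentialError(ValueError):
    pass


def normalize_to_reference(df: pd.DataFrame,
                           reference_condition: str) -> pd.DataFrame:
    """Divide each peptide's ratios by its mean ratio in the reference.

    The reference-condition mean becomes 1. Peptides whose reference
    ratios are all missing are flagged (``normalized == False``) and left
    unchanged. Normalizing twice is the identity.
    """
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise DifferentialError(f"table lacks columns {sorted(missing)}")
    if reference_condition not in set(df["condition"]):
        raise DifferentialError(
            f"reference condition {reference_condition!r} absent from table")
    out = df.copy()
    out["normalized"] = False
    for pep, grp in df.groupby("peptide", sort=False):
        ref = grp.loc[grp["condition"] == reference_condition, "ratio"]
        ref_mean = ref.dropna().mean()
        if pd.isna(ref_mean) or ref_mean == 0:
            logger.warning("peptide %s: reference condition missing, "
                           "not normalized", pep)
            continue
        sel = out["peptide"] == pep
        out.loc[sel, "ratio"] = out.loc[sel, "ratio"] / ref_mean
        out.loc[sel, "normalized"] = True
    return out


@dataclass(frozen=True)
class DifferentialResult:
    """One peptide/group contrast between two conditions."""

    key: str
    condition_a: str
    condition_b: str
    log2_fold_change: float
    p_value: float
    significant: bool
    adjusted_p: float | None = None


@dataclass(frozen=True)
class DifferentialResults:
    """Container for all per-peptide contrasts of one fit."""

    results: tuple[DifferentialResult, ...]
    alpha: float
    warnings_: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "peptide": r.key,
                "condition_a": r.condition_a,
                "condition_b": r.condition_b,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "significant": r.significant,
                "adjusted_p": r.adjusted_p,
            }
            for r in self.results
        ], columns=["peptide", "condition_a", "condition_b",
                    "log2_fold_change", "p_value", "significant",
                    "adjusted_p"])

    def summary(self) -> str:
        df = self.to_frame()
        n_sig = int(df["significant"].sum())
        lines = [
            "Differential kinase-activation results",
            "=" * 54,
            f"contrasts: {len(df)}   significant at p<={self.alpha:g}: {n_sig}",
            "",
            df.to_string(index=False,
                         float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class DifferentialModel:
    """Per-peptide condition comparison on log2 analyte/standard ratios.

    Parameters
    ----------
    data : tidy table with columns peptide, condition, bio_rep, tech_rep,
        ratio (missing ratios allowed; dropped per peptide).
    reference_condition : condition that serves as the denominator of each
        contrast; defaults to the first condition in sorted order.
    alpha : significance cutoff on the (unadjusted) p-value.
    adjust : apply Benjamini-Hochberg adjustment across peptides of each
        contrast (reported alongside; significance stays on the raw p).
    """

    def __init__(self, data: pd.DataFrame, reference_condition: str | None = None,
                 alpha: float = 0.05, adjust: bool = False):
        missing = set(REQUIRED_COLUMNS) - set(data.columns)
        if missing:
            raise DifferentialError(f"table lacks columns {sorted(missing)}")
        conditions = sorted(data["condition"].unique())
        if len(conditions) < 2:
            raise DifferentialError("need >= 2 conditions")
        self.data = data
        self.conditions = conditions
        self.reference = reference_condition or conditions[0]
        if self.reference not in conditions:
            raise DifferentialError(
                f"reference condition {self.reference!r} absent")
        self.alpha = alpha
        self.adjust = adjust

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DifferentialModel":
        return cls(df, **kwargs)

    def _bio_means(self, grp: pd.DataFrame) -> pd.Series:
        """log2-transform, then average technical reps within bio reps."""
        vals = grp.dropna(subset=["ratio"])
        vals = vals[vals["ratio"] > 0]
        log2 = np.log2(vals["ratio"])
        return log2.groupby([vals["condition"], vals["bio_rep"]]).mean()

    def fit(self) -> DifferentialResults:
        results: list[DifferentialResult] = []
        warn_msgs: list[str] = []
        contrasts = [(c, self.reference) for c in self.conditions
                     if c != self.reference]
        for pep, grp in self.data.groupby("peptide", sort=True):
            means = self._bio_means(grp)
            for cond_a, cond_b in contrasts:
                conds = means.index.get_level_values(0) if means.size else []
                a = (means.loc[cond_a].to_numpy() if cond_a in conds
                     else np.empty(0))
                b = (means.loc[cond_b].to_numpy() if cond_b in conds
                     else np.empty(0))
                if a.size == 0 or b.size == 0:
                    continue
                log2fc = float(a.mean() - b.mean())
                if a.size < 2 or b.size < 2:
                    msg = (f"{pep} {cond_a} vs {cond_b}: <2 biological "
                           "replicates, p-value not computed")
                    warnings.warn(msg, stacklevel=2)
                    warn_msgs.append(msg)
                    p = float("nan")
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                    if not np.isfinite(p):
                        # zero pooled variance: degenerate but well-defined
                        p = 1.0 if np.isclose(log2fc, 0.0) else 0.0
                results.append(DifferentialResult(
                    key=pep, condition_a=cond_a, condition_b=cond_b,
                    log2_fold_change=log2fc, p_value=p,
                    significant=bool(p <= self.alpha) if np.isfinite(p) else False,
                ))
        if self.adjust and results:
            adjusted = []
            for cond_a, cond_b in contrasts:
                sub = [r for r in results
                       if r.condition_a == cond_a and r.condition_b == cond_b]
                finite = [r for r in sub if np.isfinite(r.p_value)]
                if finite:
                    _, adj, _, _ = multipletests(
                        [r.p_value for r in finite], method="fdr_bh")
                    adj_map = {id(r): q for r, q in zip(finite, adj)}
                else:
                    adj_map = {}
                for r in sub:
                    adjusted.append(DifferentialResult(
                        key=r.key, condition_a=r.condition_a,
                        condition_b=r.condition_b,
                        log2_fold_change=r.log2_fold_change,
                        p_value=r.p_value, significant=r.significant,
                        adjusted_p=adj_map.get(id(r)),
                    ))
            results = adjusted
        return DifferentialResults(results=tuple(results), alpha=self.alpha,
                                   warnings_=tuple(warn_msgs))


def differential_test(data: pd.DataFrame, **kwargs) -> DifferentialResults:
    """Functional convenience wrapper around :class:`DifferentialModel`."""
    return DifferentialModel(data, **kwargs).fit()
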