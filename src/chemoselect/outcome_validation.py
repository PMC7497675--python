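"""Expression-vs-outcome validation: ROC dichotomization, Mann–Whitney,
Kaplan–Meier and log-rank, with FDR control across genes.

For each candidate gene, expression (z-scores) is compared between
patients who died of disease and those alive or lost to follow-up:

* AUC and an optimal cutpoint from ROC analysis (Youden's J), with the
  curve oriented so AUC >= 0.5;
* a two-sided Mann–Whitney U test on the two status groups (the ROC
  p-value, by the standard AUC/U equivalence);
* Kaplan–Meier curves and a log-rank test comparing the low- and
  high-expression groups defined by the cutpoint.

Mann–Whitney p-values are Benjamini–Hochberg adjusted across the genes
tested; a gene is significant when its raw p < 0.05 AND its adjusted
value is below the FDR threshold (a dual criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, mannwhitneyu, rankdata

from .enrichment import bh_adjust

__all__ = [
    "ExpressionCohort",
    "GeneOutcomeResult",
    "KMCurve",
    "read_cohort",
    "roc_dichotomize",
    "mann_whitney",
    "km_estimate",
    "logrank_test",
    "validate_genes",
]

DEFAULT_FDR = 0.05
_META_COLS = ("patient_id", "survival_time", "event")


@dataclass
class ExpressionCohort:
    """Per-patient expression z-scores with survival time and event status."""

    expression: pd.DataFrame  # patients x genes
    survival_time: pd.Series  # months, > 0
    event: pd.Series  # 1 = died of disease, 0 = censored

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.survival_time.index) or not (
            self.expression.index.equals(self.event.index)
        ):
            raise ValueError("expression, survival_time and event must share an index")
        if (self.survival_time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be binary")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    def __len__(self) -> int:
        return len(self.expression)


def read_cohort(path: str) -> ExpressionCohort:
    """Read a cohort TSV: patient_id, survival_time, event, <gene columns>."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    df = df.set_index("patient_id")
    genes = [c for c in df.columns if c not in _META_COLS]
    return ExpressionCohort(
        df[genes].astype(float),
        df["survival_time"].astype(float),
        df["event"].astype(int),
    )


def roc_dichotomize(values, status) -> tuple[float, float]:
    """AUC (oriented >= 0.5) and the Youden-optimal expression cutpoint.

    The cutpoint is the midpoint between adjacent observed values that
    maximises sensitivity + specificity - 1 for the oriented curve; ties
    in J break toward the more balanced split, then the lower cutpoint.
    Constant expression returns (0.5, the constant) — no informative
    split exists.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(status, dtype=int)
    if v.shape != s.shape or v.ndim != 1:
        raise ValueError("values and status must be aligned 1-d vectors")
    n1 = int(s.sum())
    n0 = len(s) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be non-empty")
    # AUC by the rank / Mann-Whitney identity
    ranks = rankdata(v)
    auc = (ranks[s == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    flipped = auc < 0.5
    if flipped:
        auc = 1.0 - auc
    uniq = np.unique(v)
    if uniq.size == 1:
        return float(auc), float(uniq[0])
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    # counts of each class at or below every candidate cut (vectorised scan)
    pos_vals = np.sort(v[s == 1])
    neg_vals = np.sort(v[s == 0])
    pos_below = np.searchsorted(pos_vals, cuts, side="right")
    neg_below = np.searchsorted(neg_vals, cuts, side="right")
    if flipped:
        # the class enriched above the cut is "alive": sens on negatives
        sens = (n0 - neg_below) / n0
        spec = pos_below / n1
    else:
        sens = (n1 - pos_below) / n1
        spec = neg_below / n0
    j = sens + spec - 1.0
    n = n0 + n1
    above = n - (pos_below + neg_below)
    balance = np.abs(above - (n - above))
    best = np.lexsort((cuts, balance, -j))[0]
    return float(auc), float(cuts[best])


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (statistic for x) and p-value.

    Exact enumeration when the pooled sample is small (<= 20) and free of
    ties; otherwise the normal approximation with tie-corrected variance
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for u in uniq:
        n_at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return KMCurve(uniq, np.asarray(surv, dtype=float))


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    With no events in either group the statistic is 0 and p = 1 by
    convention (no information).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    if len(set(g.tolist())) < 2:
        raise ValueError("log-rank requires two non-empty groups")
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        d = int(((t == u) & (e == 1)).sum())
        d1 = int(((t == u) & (e == 1) & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass(frozen=True)
class GeneOutcomeResult:
    gene: str
    auc: float
    cutpoint: float
    mw_p: float
    logrank_p: float
    q: float
    significant: bool


def validate_genes(
    cohort: ExpressionCohort,
    genes,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[GeneOutcomeResult]:
    """Run the full outcome validation for each gene in the cohort.

    Genes absent from the expression matrix are skipped (reported by
    omission from the result list).  Significance requires raw
    Mann–Whitney p < 0.05 and BH-adjusted value below ``fdr_threshold``.
    """
    tested = [g for g in genes if g in cohort.expression.columns]
    status = cohort.event.to_numpy()
    times = cohort.survival_time.to_numpy()
    rows = []
    for gene in tested:
        v = cohort.expression[gene].to_numpy()
        auc, cut = roc_dichotomize(v, status)
        died = v[status == 1]
        alive = v[status == 0]
        _, mw_p = mann_whitney(died, alive)
        hi = (v > cut).astype(int)
        if hi.sum() in (0, len(hi)):
            logrank_p = float("nan")
        else:
            _, logrank_p = logrank_test(times, status, hi)
        rows.append((gene, auc, cut, mw_p, logrank_p))
    qvals = bh_adjust([r[3] for r in rows])
    return [
        GeneOutcomeResult(
            gene, auc, cut, mw_p, logrank_p, q,
            significant=(mw_p < 0.05 and q < fdr_threshold),
        )
        for (gene, auc, cut, mw_p, logrank_p), q in zip(rows, qvals)
    ]
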