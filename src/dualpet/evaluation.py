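"""Splitting, classification metrics and statistical comparison.

Implements the evaluation protocol around the classifier: stratified
0.6/0.1/0.3 train/validation/test split over the diagnosis x amyloid-reading
strata, threshold metrics (accuracy, F1 with AD positive, G-mean), AUROC with
DeLong's variance estimate, Spearman correlation with cognition, subgroup
AUROCs within each amyloid-reading stratum, and cohort demographic summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import SubjectRecord

__all__ = [
    "SplitAssignment",
    "stratified_split",
    "classification_metrics",
    "delong_auroc",
    "spearman_corr",
    "subgroup_auroc",
    "concordance_auroc",
    "cohort_summary",
    "MetricsReport",
    "metrics_report",
]

PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # subject_id -> partition
    seed: int
    ratios: tuple[float, float, float]

    def ids(self, partition: str) -> list[str]:
        return [sid for sid, p in self.assignment.items() if p == partition]


def largest_remainder(n: int, ratios) -> list[int]:
    """Allocate n items to len(ratios) bins by largest-remainder rounding.

    Ties in the fractional remainders are broken by bin order.
    """
    exact = np.asarray(ratios, float) * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - base.sum()
    order = sorted(range(len(ratios)), key=lambda i: (-rem[i], i))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def stratified_split(
    records: list[SubjectRecord],
    ratios: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified split over diagnosis x amyloid-reading strata.

    Within each stratum subjects are shuffled with the seed and allocated by
    largest-remainder rounding of stratum_size x ratio, so every partition's
    per-stratum count is within one subject of the exact proportion.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    strata: dict[tuple, list[str]] = {}
    for r in records:
        strata.setdefault((r.diagnosis, r.ab_reading), []).append(r.subject_id)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        rng.shuffle(ids)
        counts = largest_remainder(len(ids), ratios)
        pos = 0
        for part, k in zip(PARTITIONS, counts):
            for sid in ids[pos : pos + k]:
                assignment[sid] = part
            pos += k
    return SplitAssignment(assignment=assignment, seed=seed, ratios=tuple(ratios))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, F1 (AD positive) and G-mean at a score threshold.

    G-mean is the geometric mean of sensitivity and specificity — the
    standard summary under class imbalance.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    gmean = float(np.sqrt(sens * spec)) if np.isfinite(sens * spec) else np.nan
    return {"accuracy": acc, "f1": f1, "g_mean": gmean,
            "sensitivity": sens, "specificity": spec, "threshold": threshold}


def delong_auroc(scores, labels) -> tuple[float, float]:
    """AUROC and its DeLong standard error.

    The AUROC is the Mann-Whitney statistic (ties count 1/2); the variance is
    estimated from the structural components V10 (per positive) and V01 (per
    negative): var = var(V10)/m + var(V01)/n.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # pairwise Mann-Whitney kernel
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return auc, se


def spearman_corr(scores, covariate) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    scores = np.asarray(scores, float)
    covariate = np.asarray(covariate, float)
    if scores.shape != covariate.shape or scores.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(covariate) == 0 or np.ptp(scores) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    rho = stats.spearmanr(scores, covariate).statistic
    return float(rho)


def subgroup_auroc(scores, labels, readings) -> dict[str, tuple[float, float] | None]:
    """DeLong AUROC restricted to each amyloid-reading stratum.

    Returns {"ab_neg": (auroc, se), "ab_pos": ...}; a stratum missing one
    class yields None for that entry, the other strata are still computed.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    readings = np.asarray(readings)
    out: dict[str, tuple[float, float] | None] = {}
    for key, reading in (("ab_neg", "neg"), ("ab_pos", "pos")):
        mask = readings == reading
        try:
            out[key] = delong_auroc(scores[mask], labels[mask])
        except ValueError:
            out[key] = None
    return out


def concordance_auroc(scores, labels, readings) -> dict[str, tuple[float, float] | None]:
    """AUROC within reading-concordant vs reading-discordant subjects.

    Concordant: amyloid-negative CN and amyloid-positive AD; discordant:
    amyloid-positive CN and amyloid-negative AD. A delay-phase-only
    classifier, driven by amyloid load alone, separates the concordant pair
    but inverts on the discordant one.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos_reading = (np.asarray(readings) == "pos").astype(int)
    concordant = pos_reading == labels
    out: dict[str, tuple[float, float] | None] = {}
    for key, mask in (("concordant", concordant), ("discordant", ~concordant)):
        try:
            out[key] = delong_auroc(scores[mask], labels[mask])
        except ValueError:
            out[key] = None
    return out


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def cohort_summary(records: list[SubjectRecord]) -> dict:
    """Demographic-style summary: per-diagnosis counts, amyloid readings,
    MMSE mean +/- sd, and the discordant-subgroup fractions."""
    if not records:
        raise ValueError("empty cohort")
    out: dict = {"total": len(records)}
    for dx in ("CN", "AD"):
        group = [r for r in records if r.diagnosis == dx]
        n = len(group)
        neg = sum(1 for r in group if r.ab_reading == "neg")
        pos = n - neg
        mmse = np.array([r.mmse for r in group])
        out[dx] = {
            "n": n,
            "ab_neg": neg,
            "ab_pos": pos,
            "mmse_mean": float(mmse.mean()) if n else np.nan,
            "mmse_sd": float(mmse.std(ddof=1)) if n > 1 else np.nan,
        }
    out["ab_neg_total"] = out["CN"]["ab_neg"] + out["AD"]["ab_neg"]
    out["ab_pos_total"] = out["CN"]["ab_pos"] + out["AD"]["ab_pos"]
    out["pct_abneg_ad"] = (
        100.0 * out["AD"]["ab_neg"] / out["AD"]["n"] if out["AD"]["n"] else np.nan
    )
    out["pct_abpos_cn"] = (
        100.0 * out["CN"]["ab_pos"] / out["CN"]["n"] if out["CN"]["n"] else np.nan
    )
    return out


@dataclass
class MetricsReport:
    """One model's evaluation on one subject set."""

    accuracy: float
    auroc: float
    auroc_se: float
    f1: float
    g_mean: float
    spearman_rho: float | None
    n_positive: int
    n_negative: int
    threshold: float = 0.5
    subgroups: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "auroc_se": self.auroc_se,
            "f1": self.f1,
            "g_mean": self.g_mean,
            "spearman_rho": self.spearman_rho,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "threshold": self.threshold,
            "subgroups": self.subgroups,
        }


def metrics_report(scores, labels, readings=None, mmse=None,
                   threshold: float = 0.5) -> MetricsReport:
    """Full evaluation of one score vector: threshold metrics, DeLong AUROC,
    optional MMSE correlation and amyloid-stratified subgroup AUROCs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cm = classification_metrics(scores, labels, threshold)
    auc, se = delong_auroc(scores, labels)
    rho = None
    if mmse is not None:
        rho = spearman_corr(scores, mmse)
    sub = {}
    if readings is not None:
        sub = {
            k: (None if v is None else {"auroc": v[0], "se": v[1]})
            for k, v in subgroup_auroc(scores, labels, readings).items()
        }
    return MetricsReport(
        accuracy=cm["accuracy"],
        auroc=auc,
        auroc_se=se,
        f1=cm["f1"],
        g_mean=cm["g_mean"],
        spearman_rho=rho,
        n_positive=int(labels.sum()),
        n_negative=int(len(labels) - labels.sum()),
        threshold=threshold,
        subgroups=sub,
    )
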