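"""Scar labelling, differential strain, ROC/cut-off, ICC and group statistics.

The detection endpoint is a per-segment scar area fraction above 50% (the
late-gadolinium-enhancement transmurality proxy); a segment counts as scarred
at all when its fraction exceeds 1%. ROC analysis treats segments, not
subjects, as the unit: scar-group segments above the endpoint are positives,
all control-group segments are negatives, and within-subject clustering is
deliberately ignored.

Scores are oriented so that larger means more scar-like before the ROC is
computed: shortening strains (circumferential, longitudinal) become less
negative with scar, so the raw value already points the right way; radial
thickening strains shrink with scar and are negated. Differential strain
(control-group segmental mean minus the measured value) flips both rules.
The reported cut-off is mapped back to the natural strain scale together
with the comparison rule.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

__all__ = [
    "TRANSMURALITY_BINS",
    "RocResult",
    "IccResult",
    "transmurality_bin",
    "scar_table",
    "build_reference",
    "differential_strain",
    "orientation_sign",
    "roc",
    "strain_roc",
    "icc",
    "group_compare",
]

TRANSMURALITY_BINS = ("none", "1-25%", "26-50%", "51-75%", ">75%")

SCAR_FLAG_THRESHOLD = 0.01
ENDPOINT_THRESHOLD = 0.50

#: +1 when larger raw strain is more scar-like, -1 otherwise.
_RAW_ORIENTATION = {
    "circumferential": +1.0,
    "longitudinal": +1.0,
    "radial_sa": -1.0,
    "radial_la": -1.0,
}


def transmurality_bin(fraction: float) -> tuple[str, bool, bool]:
    """Transmurality bin, scar flag (>1%) and endpoint flag (>50%).

    Bins partition (0.01, 1] into 1-25%, 26-50%, 51-75% and >75%; fractions
    of at most 1% are "none" (not scar).
    """
    f = float(fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("scar fraction must lie in [0, 1]")
    scar = f > SCAR_FLAG_THRESHOLD
    endpoint = f > ENDPOINT_THRESHOLD
    if not scar:
        b = "none"
    elif f <= 0.25:
        b = "1-25%"
    elif f <= 0.50:
        b = "26-50%"
    elif f <= 0.75:
        b = "51-75%"
    else:
        b = ">75%"
    return b, scar, endpoint


def scar_table(fractions_by_subject: dict) -> pd.DataFrame:
    """Per-(subject, segment) scar table from 16-element fraction arrays."""
    rows = []
    for sid, fracs in fractions_by_subject.items():
        fracs = np.asarray(fracs, dtype=float)
        if fracs.shape != (16,):
            raise ValueError("each subject needs 16 per-segment scar fractions")
        for seg in range(1, 17):
            b, scar, endpoint = transmurality_bin(fracs[seg - 1])
            rows.append({"subject_id": sid, "segment_id": seg,
                         "scar_fraction": float(fracs[seg - 1]),
                         "transmurality_bin": b, "scar": scar,
                         "endpoint": endpoint})
    return pd.DataFrame(rows)


def build_reference(strain_table: pd.DataFrame, control_ids) -> pd.DataFrame:
    """Control-group mean and SD per (segment, layer, direction).

    Only subjects in ``control_ids`` contribute; non-missing values only.
    Cells backed by fewer than two control subjects get SD = NaN.
    """
    control_ids = set(control_ids)
    if not control_ids:
        raise ValueError("no control subjects supplied")
    ctrl = strain_table[strain_table["subject_id"].isin(control_ids)
                        & ~strain_table["missing"]]
    if ctrl.empty:
        raise ValueError("no usable control measurements")
    ref = (ctrl.groupby(["segment_id", "layer", "direction"])["strain_pct"]
           .agg(reference_mean="mean",
                reference_sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n_controls="count")
           .reset_index())
    return ref


def differential_strain(measured, reference_mean, *, convention: str = "reference-minus-measured"):
    """Differential strain relative to the control reference.

    The default convention is the literal definition: control-group mean for
    that (segment, layer, direction) minus the measured value, so a patient
    measuring exactly at the reference scores 0. The alternative
    ``"measured-minus-reference"`` flips the sign. Missing inputs propagate.
    """
    measured = np.asarray(measured, dtype=float)
    reference_mean = np.asarray(reference_mean, dtype=float)
    if convention == "reference-minus-measured":
        return reference_mean - measured
    if convention == "measured-minus-reference":
        return measured - reference_mean
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class RocResult:
    """ROC summary for one oriented score."""

    auc: float
    cutoff: float                  # threshold on the oriented score
    sensitivity: float
    specificity: float             # achieved, >= requested
    requested_specificity: float
    n_positive: int
    n_negative: int
    orientation: float = 1.0       # sign applied to the natural-scale value
    cutoff_natural: float | None = None
    rule: str = ""                 # e.g. "strain >= -15.0"


def roc(scores, labels, *, specificity: float = 0.80) -> RocResult:
    """ROC/AUC of an oriented score (larger = more scar-like).

    AUC equals the Mann-Whitney U statistic divided by ``n_pos * n_neg``,
    with ties counted one half. The cut-off is the smallest observed score
    ``t`` (classify positive when ``score >= t``) whose specificity is at
    least the requested level — "at least the level, closest from above" —
    which maximizes sensitivity subject to the specificity constraint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    auc = float(roc_auc_score(labels, scores))

    pos = scores[labels]
    neg = scores[~labels]
    candidates = np.unique(scores)
    cutoff = None
    for t in candidates:  # ascending; first feasible maximizes sensitivity
        spec = float((neg < t).mean())
        if spec >= specificity:
            cutoff = float(t)
            break
    if cutoff is None:  # all thresholds too permissive; step above the max
        cutoff = float(candidates[-1]) + np.spacing(abs(candidates[-1]) + 1.0)
    sens = float((pos >= cutoff).mean())
    spec = float((neg < cutoff).mean())
    return RocResult(auc=auc, cutoff=cutoff, sensitivity=sens, specificity=spec,
                     requested_specificity=specificity, n_positive=n_pos,
                     n_negative=n_neg)


def orientation_sign(direction: str, *, differential: bool = False) -> float:
    """Sign making larger oriented score = more scar-like."""
    try:
        s = _RAW_ORIENTATION[direction]
    except KeyError:
        raise ValueError(f"unknown strain direction {direction!r}") from None
    return -s if differential else s


def strain_roc(values, labels, direction: str, *, differential: bool = False,
               specificity: float = 0.80) -> RocResult:
    """ROC of strain values with the direction's scar orientation applied.

    The returned cut-off is expressed on the natural strain (or differential)
    scale, with the comparison rule spelled out: e.g. circumferential strain
    classifies scar when ``strain >= cutoff`` (less negative than cut-off),
    radial when ``strain <= cutoff``.
    """
    sign = orientation_sign(direction, differential=differential)
    values = np.asarray(values, dtype=float)
    res = roc(sign * values, labels, specificity=specificity)
    res.orientation = sign
    res.cutoff_natural = sign * res.cutoff
    quantity = "differential" if differential else "strain"
    res.rule = f"{quantity} {'>=' if sign > 0 else '<='} {res.cutoff_natural:.4g}"
    return res


@dataclass
class IccResult:
    """Intraclass correlation, two-way random, absolute agreement, single measures."""

    icc: float
    ci95: tuple[float, float]
    model: str = "ICC(2,1) two-way random, absolute agreement, single measures"
    n_subjects: int = 0
    n_raters: int = 0
    n_dropped: int = 0


def icc(ratings, *, alpha: float = 0.05) -> IccResult:
    """ICC(2,1) with the Shrout-Fleiss 95% confidence interval.

    ``ratings`` is an (n_subjects, k_raters) table; rows containing missing
    cells are dropped (and counted). Requires at least two subjects, two
    raters and non-zero total variance.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) array")
    complete = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~complete).sum())
    X = X[complete]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires at least 2 subjects and 2 raters")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom

    if mse <= 0 and msc <= 0:  # perfect agreement, degenerate F ratios
        lo = hi = value
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * value * fj + n * (1 + (k - 1) * value) - k * value) ** 2
        vd = ((n - 1) * k ** 2 * value ** 2 * fj ** 2
              + (n * (1 + (k - 1) * value) - k * value) ** 2)
        v = vn / vd
        f_l = sstats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sstats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        lo = min(lo, value)
        hi = max(hi, value)
    return IccResult(icc=float(value), ci95=(float(lo), float(hi)),
                     n_subjects=n, n_raters=k, n_dropped=n_dropped)


def group_compare(groups: dict, *, min_per_group: int = 2):
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Empty (or all-NaN) groups are excluded. Adjusted p-values are the raw
    two-sided t-test p-values multiplied by the number of pairwise
    comparisons, capped at 1.

    Returns
    -------
    anova : dict with keys ``f``, ``p``, ``groups``
    pairwise : DataFrame with one row per group pair
    """
    clean = {}
    excluded = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= min_per_group:
            clean[name] = v
        else:
            excluded.append(name)
    if len(clean) < 2:
        raise ValueError("need at least two non-empty groups")
    names = list(clean)
    f_stat, p_anova = sstats.f_oneway(*clean.values())
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = sstats.ttest_ind(clean[a], clean[b])
        rows.append({"group_a": a, "group_b": b,
                     "mean_a": float(clean[a].mean()), "mean_b": float(clean[b].mean()),
                     "n_a": int(clean[a].size), "n_b": int(clean[b].size),
                     "p_raw": float(p), "p_bonferroni": float(min(1.0, p * m))})
    anova = {"f": float(f_stat), "p": float(p_anova), "groups": names,
             "excluded": excluded}
    return anova, pd.DataFrame(rows)
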