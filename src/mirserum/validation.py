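"""Per-patient biomarker validation: Student's t on delta-Ct and ROC/AUC.

The screening arm works on pooled replicates; validation re-measures a
selected marker on every individual patient.  Group separation is tested
with the classical pooled-variance Student t (Welch available by flag), and
diagnostic performance is summarized by the ROC curve and its area.  The
AUC is computed by the rank (Mann-Whitney) estimator with half-credit for
ties — it equals the probability that a random case outranks a random
control and is invariant under monotone transforms of the marker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def group_ttest(values_case, values_control, welch: bool = False):
    """Two-sided two-sample t-test on per-sample delta-Ct values.

    Returns ``(t, p, fold_change)`` with FC = 2^(−(mean_case − mean_control)),
    so FC > 1 means up-regulation in cases on the Ct scale.  Degenerate
    zero-variance data yields t = 0, p = 1 when the means agree.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    delta = a.mean() - b.mean()
    fc = float(2.0 ** (-delta))
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p), fc
    d = a.size + b.size - 2
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / d
    se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    if se == 0:
        t = 0.0 if delta == 0 else np.sign(delta) * np.inf
        p = 1.0 if delta == 0 else 0.0
    else:
        t = float(delta / se)
        p = float(2.0 * stats.t.sf(abs(t), d))
    return t, p, fc


@dataclass
class RocCurve:
    """ROC sweep of a scalar marker plus its Mann-Whitney AUC.

    ``direction`` records the positive-class convention actually used:
    ``lower_is_positive`` means smaller marker values (fewer cycles, more
    template) call a case.  Thresholds are on the marker scale; sensitivity
    and specificity are fractions in [0, 1].
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str


def _rank_auc(case_scores, control_scores) -> float:
    """Mann-Whitney AUC with half-credit ties via midranks."""
    pooled = np.concatenate([case_scores, control_scores])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(case_scores), len(control_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_auc(cases, controls, direction: str = "auto") -> RocCurve:
    """ROC curve and AUC for a marker measured in cases and controls.

    ``direction`` is ``lower_is_positive``, ``higher_is_positive`` or
    ``auto`` (pick the orientation with AUC >= 0.5; logged).
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([cases, controls]) == np.concatenate([cases, controls])[0]):
        warnings.warn("all marker values identical; AUC degenerates to 0.5")
        return RocCurve(
            thresholds=np.array([cases[0]]),
            sensitivity=np.array([1.0]),
            specificity=np.array([0.0]),
            auc=0.5,
            direction="higher_is_positive" if direction == "auto" else direction,
        )

    if direction == "auto":
        auc_hi = _rank_auc(cases, controls)
        direction = "higher_is_positive" if auc_hi >= 0.5 else "lower_is_positive"
        logger.info("roc_auc: auto-selected convention %s", direction)
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")

    sign = -1.0 if direction == "lower_is_positive" else 1.0
    cs, ks = sign * cases, sign * controls
    auc = _rank_auc(cs, ks)

    # sweep: call positive when score >= threshold, thresholds descending
    thr_scores = np.concatenate([[np.inf], np.unique(np.concatenate([cs, ks]))[::-1]])
    sens = np.array([(cs >= t).mean() for t in thr_scores])
    spec = np.array([(ks < t).mean() for t in thr_scores])
    return RocCurve(
        thresholds=sign * thr_scores,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        direction=direction,
    )
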