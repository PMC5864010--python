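"""Two-group differential expression: moderated t, fold change, sampling p,
candidate selection and intersections.

Sign convention (Ct scale): the group difference Δ = mean(case) − mean(control)
is on the cycle scale, where *more* cycles means *less* template; the linear
fold change is therefore FC = 2^(−Δ), so Δ > 0 reads "down-regulated in
cases" (FC < 1) and Δ < 0 "up-regulated" (FC > 1).

The "sampling p" is a permutation control on the model p-value: values are
permuted across features within each sample group, the moderated-t analysis
is rerun per permutation, and all null p-values are pooled; a feature's
sampling p is the fraction of the null pool at or below its observed model p.
Candidates are the features whose sampling p stays below α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtTable, SampleSheet, ValidationError
from .normalization import NormalizedTable
from .stats import moderated_stats, pooled_permutation_p

logger = logging.getLogger(__name__)

DEFAULT_B = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """A named case-vs-control contrast within one analysis branch."""

    name: str
    case: str
    control: str
    branch: str = "raw"  # or "ipc_delta_ct"

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValidationError("case and control groups must differ")

    @classmethod
    def from_spec(cls, spec: str, branch: str = "raw") -> "GroupComparison":
        """Parse ``"control:case"`` (e.g. ``"normal:mild"``)."""
        control, _, case = spec.partition(":")
        if not case:
            raise ValueError(f"comparison spec {spec!r} must be 'control:case'")
        return cls(name=f"{control}_vs_{case}", case=case, control=control, branch=branch)


@dataclass
class ModeratedTFit:
    """Per-feature moderated-t results plus the shared variance prior.

    The posterior variance satisfies
    ``s2_post = (d0*s0sq + d*s2) / (d0 + d)`` for finite ``d0``; ``d0 = inf``
    denotes complete shrinkage, ``s2_post = s0sq``.
    """

    comparison: GroupComparison
    table: pd.DataFrame  # index features; columns mean_case, mean_control, delta, s2, s2_post, t, p
    d: int
    d0: float
    s0sq: float


def _values_of(data) -> pd.DataFrame:
    if isinstance(data, CtTable):
        return data.values
    if isinstance(data, NormalizedTable):
        return data.values
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError(f"expected CtTable, NormalizedTable or DataFrame, got {type(data)!r}")


def _group_indices(values: pd.DataFrame, sheet: SampleSheet, comparison: GroupComparison):
    cols = list(values.columns)
    idx_a = [cols.index(s) for s in sheet.samples_of(comparison.case) if s in cols]
    idx_b = [cols.index(s) for s in sheet.samples_of(comparison.control) if s in cols]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError(
            f"comparison {comparison.name!r} needs >= 2 samples per group "
            f"(got {len(idx_a)} case, {len(idx_b)} control)"
        )
    return np.array(idx_a), np.array(idx_b)


def fit_moderated_t(data, sheet: SampleSheet, comparison: GroupComparison, d0=None) -> ModeratedTFit:
    """Fit the moderated two-group model for one comparison.

    ``d0=0`` forces the ordinary pooled-variance Student t (no shrinkage);
    by default the prior (d0, s0sq) is estimated across features by method
    of moments on ``log s2``.
    """
    values = _values_of(data)
    if len(values.index) < 2 and d0 is None:
        raise ValidationError("moderation borrows strength across features; need >= 2 features")
    idx_a, idx_b = _group_indices(values, sheet, comparison)
    arr = values.to_numpy(dtype=float)
    res = moderated_stats(arr[:, idx_a], arr[:, idx_b], d0=d0)
    table = pd.DataFrame(
        {
            "mean_case": res["mean_a"],
            "mean_control": res["mean_b"],
            "delta": res["delta"],
            "s2": res["s2"],
            "s2_post": res["s2_post"],
            "t": res["t"],
            "p": res["p"],
        },
        index=values.index,
    )
    return ModeratedTFit(
        comparison=comparison,
        table=table,
        d=int(res["d"]),
        d0=float(res["d0"]),
        s0sq=float(res["s0sq"]),
    )


def fold_change(delta):
    """Linear fold change from a Ct-scale group difference: FC = 2^(−Δ)."""
    return 2.0 ** (-np.asarray(delta, dtype=float)) if np.ndim(delta) else float(2.0 ** (-delta))


def sampling_p(
    data,
    sheet: SampleSheet,
    comparison: GroupComparison,
    B: int = DEFAULT_B,
    seed: int | None = None,
    smoothing: bool = False,
) -> pd.Series:
    """Permutation sampling p per feature (see module docstring).

    ``seed`` is mandatory: the permutation stream must be reproducible.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if seed is None:
        raise ValidationError("sampling_p requires an explicit seed")
    values = _values_of(data)
    idx_a, idx_b = _group_indices(values, sheet, comparison)
    rng = np.random.default_rng(seed)
    p = pooled_permutation_p(
        values.to_numpy(dtype=float), idx_a, idx_b, B=B, rng=rng, smoothing=smoothing
    )
    return pd.Series(p, index=values.index, name="sampling_p")


def build_diff_table(fit: ModeratedTFit, sampling: pd.Series) -> pd.DataFrame:
    """Assemble the per-feature report: dCt difference, FC, model p, sampling p.

    Rows are ranked ascending by sampling p (model p, then name, as
    tie-breaks) — most significant first.
    """
    df = pd.DataFrame(
        {
            "dCt": fit.table["delta"],
            "FC": fold_change(fit.table["delta"].to_numpy()),
            "p value": fit.table["p"],
            "sampling p": sampling.reindex(fit.table.index),
        }
    )
    df.index.name = "MicroRNA Name"
    order = df.reset_index().sort_values(
        ["sampling p", "p value", "MicroRNA Name"]
    )["MicroRNA Name"]
    return df.loc[order]


@dataclass
class CandidateSet:
    """Features surviving the sampling-p cut, with regulation direction.

    ``members`` is an ordered list of (feature, direction) with direction
    ``"up"`` iff FC > 1 (negative Δ, higher in cases).
    """

    comparison: str
    branch: str
    members: list[tuple[str, str]]
    alpha: float = DEFAULT_ALPHA

    @property
    def names(self) -> set[str]:
        return {f for f, _ in self.members}

    def direction_of(self, feature: str) -> str:
        for f, direction in self.members:
            if f == feature:
                return direction
        raise KeyError(feature)

    def __len__(self) -> int:
        return len(self.members)


def select_candidates(
    diff: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    comparison: str = "",
    branch: str = "",
) -> CandidateSet:
    """Select features with sampling p < alpha, ordered most significant first."""
    if "sampling p" not in diff.columns:
        raise ValidationError("diff table lacks a 'sampling p' column")
    hits = diff[diff["sampling p"] < alpha]
    hits = hits.reset_index().sort_values(["sampling p", "p value", "MicroRNA Name"])
    members = [
        (row["MicroRNA Name"], "up" if row["FC"] > 1.0 else "down")
        for _, row in hits.iterrows()
    ]
    return CandidateSet(comparison=comparison, branch=branch, members=members, alpha=alpha)


def intersect_candidates(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Name-wise intersection; features whose direction disagrees are dropped
    (logged as conflicts).  Ordering follows the first argument."""
    b_dir = dict(b.members)
    members = []
    for f, direction in a.members:
        if f not in b_dir:
            continue
        if b_dir[f] != direction:
            logger.warning("direction conflict for %s (%s vs %s); dropped", f, direction, b_dir[f])
            continue
        members.append((f, direction))
    return CandidateSet(
        comparison=f"{a.comparison}&{b.comparison}" if a.comparison != b.comparison else a.comparison,
        branch=f"{a.branch}&{b.branch}" if a.branch != b.branch else a.branch,
        members=members,
        alpha=min(a.alpha, b.alpha),
    )


def write_diff_table(diff: pd.DataFrame, path) -> None:
    """Write the candidate report TSV (MicroRNA Name, dCt, FC, p value, sampling p)."""
    out = diff.reset_index()[["MicroRNA Name", "dCt", "FC", "p value", "sampling p"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
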