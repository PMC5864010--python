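"""Reference-gene stability ranking and mean-of-reference delta-Ct scaling.

delta-Ct normalization divides out per-sample effects (input amount, RT
efficiency) by subtracting, within each sample, the mean Ct of a small set
of stably expressed reference assays:

    dCt(f, s) = Ct(f, s) - mean_r Ct(r, s).

The shipped default reference set is the three serum-stable miRNAs
miR-103a-3p, miR-423-5p and miR-191-5p; the classic non-miRNA small RNAs
(SNORD38B, SNORD49A, U6) are accepted as candidates but are typically absent
or low in serum and are not in the default set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CtTable, ValidationError
from .names import normalize_mirna_name

logger = logging.getLogger(__name__)

DEFAULT_REFERENCES = ("hsa-miR-103a-3p", "hsa-miR-423-5p", "hsa-miR-191-5p")


@dataclass
class ReferenceSet:
    """A validated reference-gene set with its per-sample mean Ct."""

    members: list[str]
    per_sample_mean: pd.Series  # index = samples, cycles


@dataclass
class NormalizedTable:
    """Feature x sample delta-Ct matrix (signed cycles)."""

    values: pd.DataFrame
    provenance: str = "ipc_delta_ct"  # or "raw"

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def make_reference_set(table: CtTable, members=DEFAULT_REFERENCES) -> ReferenceSet:
    """Validate reference members on a table and compute per-sample means.

    Every member must be present and uncensored in every sample; a censored
    reference well would silently bias every dCt in that sample.
    """
    members = [normalize_mirna_name(m) for m in members]
    if not members:
        raise ValidationError("reference set is empty")
    missing = [m for m in members if m not in table.values.index]
    if missing:
        raise ValidationError(f"reference feature {missing[0]!r} not in table")
    cens = table.censored.loc[members]
    if cens.to_numpy().any():
        f = cens.index[cens.any(axis=1)][0]
        s = cens.columns[cens.loc[f]][0]
        raise ValidationError(f"reference {f!r} censored in sample {s!r}")
    mean = table.values.loc[members].mean(axis=0)
    return ReferenceSet(members=members, per_sample_mean=mean)


def rank_reference_stability(table: CtTable, candidates) -> list[tuple[str, float]]:
    """Rank candidate references by cross-sample SD of Ct (lower = stabler).

    Candidates with any censored observation are excluded with a warning —
    an assay that drops out cannot serve as a scaling anchor.
    """
    if len(table.samples) < 2:
        raise ValidationError("stability ranking needs >= 2 samples")
    scored = []
    for c in candidates:
        c = normalize_mirna_name(c)
        if c not in table.values.index:
            raise ValidationError(f"candidate {c!r} not in table")
        if table.censored.loc[c].any():
            warnings.warn(f"reference candidate {c!r} has censored wells; excluded")
            continue
        sd = float(table.values.loc[c].std(ddof=1))
        scored.append((c, sd))
    scored.sort(key=lambda fs: (fs[1], fs[0]))
    return scored


def delta_ct(table: CtTable, refs: ReferenceSet) -> NormalizedTable:
    """Subtract the per-sample reference mean from every feature's Ct.

    References themselves are included in the output; by construction their
    per-sample mean dCt is zero.
    """
    missing = [s for s in table.samples if s not in refs.per_sample_mean.index]
    if missing:
        raise ValidationError(f"reference set lacks sample {missing[0]!r}")
    values = table.values.sub(refs.per_sample_mean[table.samples], axis=1)
    return NormalizedTable(values=values, provenance="ipc_delta_ct")
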