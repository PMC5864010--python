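"""In-memory containers for qPCR panel data.

The raw substrate of the pipeline is a feature x sample matrix of
cycle-threshold (Ct) values.  Ct is a log2-scale abundance readout: one cycle
less means roughly twice the template.  Instruments report a ceiling (here 40
cycles); a reaction that never crosses threshold is *right-censored* at the
ceiling, stored as exactly 40.0 with a censoring flag, never as missing.

Each feature carries a role — ``target`` (a measured miRNA), ``reference``
(a stable assay used for delta-Ct scaling), ``ipc`` (inter-plate calibrator
spike present on every plate) or ``other_control`` — and a panel assignment
(``I`` or ``II``, the two physical assay plates of the 752-miRNA serum panel).
Each (feature, sample) well additionally knows its plate, the unit on which
inter-plate calibration operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_CEILING = 40.0

ROLES = ("target", "reference", "ipc", "other_control")
PANELS = ("I", "II")


class ValidationError(ValueError):
    """A container invariant is violated; message names the offending cell."""


@dataclass
class CtTable:
    """Feature x sample matrix of Ct values with roles, panels and plates.

    Parameters
    ----------
    values
        DataFrame of Ct values (cycles), index = feature names, columns =
        sample names.  All values must lie in ``(0, ceiling]``.
    censored
        Boolean DataFrame, same shape; True marks wells at the detection
        ceiling.  Censored cells must hold exactly ``ceiling``.
    roles
        Series mapping feature -> role (one of :data:`ROLES`).
    panels
        Series mapping feature -> panel (one of :data:`PANELS`).
    plates
        DataFrame of plate identifiers per (feature, sample) well.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    roles: pd.Series
    panels: pd.Series
    plates: pd.DataFrame
    ceiling: float = CT_CEILING

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def features_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    def subset(self, features) -> "CtTable":
        features = list(features)
        return CtTable(
            values=self.values.loc[features].copy(),
            censored=self.censored.loc[features].copy(),
            roles=self.roles.loc[features].copy(),
            panels=self.panels.loc[features].copy(),
            plates=self.plates.loc[features].copy(),
            ceiling=self.ceiling,
        )

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate feature {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample {dup!r}")
        for df, what in ((self.censored, "censoring flags"), (self.plates, "plate map")):
            if not (df.index.equals(self.values.index) and df.columns.equals(self.values.columns)):
                raise ValidationError(f"{what} not aligned with the Ct matrix")
        for s, what in ((self.roles, "role"), (self.panels, "panel")):
            if not s.index.equals(self.values.index):
                raise ValidationError(f"{what} assignment not aligned with features")
        bad_role = set(self.roles.unique()) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown role token {sorted(bad_role)[0]!r}")
        bad_panel = set(self.panels.unique()) - set(PANELS)
        if bad_panel:
            raise ValidationError(f"unknown panel token {sorted(bad_panel)[0]!r}")
        vals = self.values.to_numpy(dtype=float)
        cens = self.censored.to_numpy(dtype=bool)
        if np.any(~np.isfinite(vals)):
            f, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite Ct at ({self.values.index[f]!r}, {self.values.columns[s]!r})"
            )
        if np.any(vals <= 0) or np.any(vals > self.ceiling):
            f, s = np.argwhere((vals <= 0) | (vals > self.ceiling))[0]
            raise ValidationError(
                f"Ct out of (0, {self.ceiling}] at "
                f"({self.values.index[f]!r}, {self.values.columns[s]!r})"
            )
        if np.any(cens & (vals != self.ceiling)):
            f, s = np.argwhere(cens & (vals != self.ceiling))[0]
            raise ValidationError(
                f"censored cell not at ceiling at "
                f"({self.values.index[f]!r}, {self.values.columns[s]!r})"
            )

    def n_censored(self) -> int:
        return int(self.censored.to_numpy().sum())


@dataclass
class SampleSheet:
    """Sample -> (group, replicate) design table.

    The study design pools patients of each severity group (normal, mild,
    moderate, severe) into a small number of disjoint biological replicates;
    ``replicate`` is the 1-based pool index within the group.
    """

    table: pd.DataFrame  # columns: sample, group, replicate

    GROUPS = ("normal", "mild", "moderate", "severe")

    def __post_init__(self) -> None:
        required = {"sample", "group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample {dup!r} in sample sheet")
        bad = set(self.table["group"]) - set(self.GROUPS)
        if bad:
            raise ValidationError(f"unknown group label {sorted(bad)[0]!r}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_of(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])

    def check_covers(self, ct: CtTable) -> None:
        missing = set(ct.samples) - set(self.samples)
        if missing:
            raise ValidationError(f"samples missing from sheet: {sorted(missing)}")


@dataclass
class TargetMap:
    """Validated miRNA -> gene-target interaction pairs (ENTREZ integer ids)."""

    pairs: pd.DataFrame  # columns: mirna, gene[, evidence]
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if not {"mirna", "gene"} <= set(self.pairs.columns):
            raise ValidationError("target map needs columns 'mirna' and 'gene'")
        if (self.pairs["gene"].astype(int) <= 0).any():
            bad = self.pairs.loc[self.pairs["gene"].astype(int) <= 0].iloc[0]
            raise ValidationError(f"non-positive gene id {bad['gene']} for {bad['mirna']!r}")
        if self.pairs.duplicated(subset=["mirna", "gene"]).any():
            raise ValidationError("duplicate (mirna, gene) pairs after load")

    def genes_of(self, mirna: str) -> set[int]:
        return set(self.pairs.loc[self.pairs["mirna"] == mirna, "gene"].astype(int))

    @property
    def mirnas(self) -> set[str]:
        return set(self.pairs["mirna"])


@dataclass
class TermMap:
    """Pathway term -> gene-set membership over a declared background.

    ``background_size`` is N, the size of the universe the enrichment test
    conditions on (e.g. the whole annotated transcriptome); it is a required
    datum of the map because it is a property of the annotation release, not
    of this package.
    """

    terms: dict[str, set[int]]
    background_size: int

    def __post_init__(self) -> None:
        union: set[int] = set()
        for term, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")
            union |= genes
        if self.background_size < len(union):
            raise ValidationError(
                f"background N={self.background_size} smaller than union of term sets ({len(union)})"
            )
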