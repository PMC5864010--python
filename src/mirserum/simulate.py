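"""Synthetic serum-panel Ct experiments with the structure the pipeline assumes.

The generator emulates a two-panel miRNA qPCR screen: ~372 + ~367 target
assays, four severity groups with two pooled biological replicates each,
one inter-plate-calibrator well per physical plate, three low-variance
reference miRNAs, additive group effects ("spikes") on selected targets,
and right-censoring at the 40-cycle instrument ceiling.

Error model: Ct is a cycle count on a log2 abundance scale, so noise is
additive Gaussian on the Ct scale —

    Ct(f, s) = baseline(f) + plate_effect(plate(f, s)) + spike(f, group(s)) + e,
    e ~ N(0, sigma_e),

with references generated at sigma_ref << sigma_e and IPC wells sharing one
true value across plates (sigma_ipc spread).  Values at or above the ceiling
are stored as exactly 40.0 and flagged censored (censoring, not truncation,
so the expression filter sees the data exactly as an instrument would
report it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtTable, SampleSheet
from .names import normalize_mirna_name
from .normalization import DEFAULT_REFERENCES


@dataclass
class SimConfig:
    """Study-condition parameters of the generator (cycles unless noted).

    Defaults model a clean two-panel serum run: uniform per-feature baselines
    in 22-38 cycles, 0.25-cycle replicate noise, plate effects small enough
    to pass the 0.05-cycle IPC gate, and no group effects unless ``spikes``
    names them (each spike is (feature, group, delta) with delta on the Ct
    scale, so a spike of -4.7 is a ~26-fold up-regulation).
    """

    n_targets_panel_i: int = 372
    n_targets_panel_ii: int = 367
    groups: tuple[str, ...] = ("normal", "mild", "moderate", "severe")
    pools_per_group: int = 2
    baseline_low: float = 22.0
    baseline_high: float = 38.0
    sigma_e: float = 0.25
    sigma_plate: float = 0.02
    sigma_ref: float = 0.08
    ref_baseline_low: float = 20.0
    ref_baseline_high: float = 26.0
    ipc_value: float = 20.0
    sigma_ipc: float = 0.01
    spikes: list[tuple[str, str, float]] = field(default_factory=list)
    ceiling: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_e", "sigma_plate", "sigma_ref", "sigma_ipc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pools_per_group < 1:
            raise ValueError("pools_per_group must be >= 1")


OTHER_CONTROLS = ("SNORD38B", "SNORD49A", "U6-snRNA")


def target_names(config: SimConfig) -> tuple[list[str], list[str]]:
    """Deterministic panel-I / panel-II target feature names."""
    p1 = [f"hsa-miR-i{k:04d}" for k in range(1, config.n_targets_panel_i + 1)]
    p2 = [f"hsa-miR-ii{k:04d}" for k in range(1, config.n_targets_panel_ii + 1)]
    return p1, p2


def simulate_experiment(config: SimConfig) -> tuple[CtTable, SampleSheet, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns the Ct table, its sample sheet, and a truth table (columns
    ``feature, group, delta``) listing every nonzero spiked effect.
    """
    rng = np.random.default_rng(config.seed)
    p1, p2 = target_names(config)
    targets = p1 + p2
    refs = list(DEFAULT_REFERENCES)
    others = list(OTHER_CONTROLS)
    ipcs = ["UniSp3-IPC-I", "UniSp3-IPC-II"]

    features = p1 + refs + others + ["UniSp3-IPC-I"] + p2 + ["UniSp3-IPC-II"]
    roles = {f: "target" for f in targets}
    roles.update({f: "reference" for f in refs})
    roles.update({f: "other_control" for f in others})
    roles.update({f: "ipc" for f in ipcs})
    panels = {f: "I" for f in p1 + refs + others + ["UniSp3-IPC-I"]}
    panels.update({f: "II" for f in p2 + ["UniSp3-IPC-II"]})

    samples = [f"{g}-{r}" for g in config.groups for r in range(1, config.pools_per_group + 1)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": samples,
                "group": [s.rsplit("-", 1)[0] for s in samples],
                "replicate": [int(s.rsplit("-", 1)[1]) for s in samples],
            }
        )
    )

    baseline = {}
    for f in targets:
        baseline[f] = rng.uniform(config.baseline_low, config.baseline_high)
    for f in refs + others:
        baseline[f] = rng.uniform(config.ref_baseline_low, config.ref_baseline_high)

    plate_ids = sorted({f"{panels[f]}-{s}" for f in features for s in samples})
    plate_effect = {p: rng.normal(0.0, config.sigma_plate) for p in plate_ids}

    spike: dict[tuple[str, str], float] = {}
    truth_rows = []
    for feat, group, delta in config.spikes:
        feat = normalize_mirna_name(feat)
        if feat not in roles or roles[feat] != "target":
            raise ValueError(f"spike feature {feat!r} is not a simulated target")
        if group not in config.groups:
            raise ValueError(f"spike group {group!r} not in configured groups")
        spike[(feat, group)] = spike.get((feat, group), 0.0) + delta
    for (feat, group), delta in spike.items():
        if delta != 0.0:
            truth_rows.append({"feature": feat, "group": group, "delta": delta})

    values = pd.DataFrame(index=features, columns=samples, dtype=float)
    censored = pd.DataFrame(False, index=features, columns=samples)
    plates = pd.DataFrame("", index=features, columns=samples, dtype=object)
    group_of = dict(zip(sheet.table["sample"], sheet.table["group"]))

    for f in features:
        role = roles[f]
        for s in samples:
            plate = f"{panels[f]}-{s}"
            plates.at[f, s] = plate
            if role == "ipc":
                ct = config.ipc_value + plate_effect[plate] + rng.normal(0.0, config.sigma_ipc)
            else:
                sigma = config.sigma_ref if role in ("reference", "other_control") else config.sigma_e
                ct = baseline[f] + plate_effect[plate] + rng.normal(0.0, sigma)
                ct += spike.get((f, group_of[s]), 0.0)
            if ct >= config.ceiling:
                values.at[f, s] = config.ceiling
                censored.at[f, s] = True
            else:
                values.at[f, s] = max(ct, 1e-6)

    table = CtTable(
        values=values,
        censored=censored,
        roles=pd.Series(roles).loc[features],
        panels=pd.Series(panels).loc[features],
        plates=plates,
        ceiling=config.ceiling,
    )
    truth = pd.DataFrame(truth_rows, columns=["feature", "group", "delta"])
    return table, sheet, truth
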