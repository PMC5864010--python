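"""Inter-plate calibrator QC, additive calibration, and the expression filter.

Every physical plate carries a synthetic spike (UniSp3-style IPC) that should
read out identically everywhere; the spread of plate-level IPC means is the
run's quality gate (strict SD < 0.05 cycles), and the per-plate deviation
from the global IPC mean is the additive calibration factor CF applied to
every well of that plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtTable, ValidationError

logger = logging.getLogger(__name__)

IPC_SD_THRESHOLD = 0.05


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationReport:
    """Per-plate IPC summary and calibration factors.

    ``factors[plate]`` is CF = global IPC mean - plate IPC mean (cycles);
    adding CF to every well of the plate equalizes the plate IPC means.
    ``passed`` is the strict gate ``ipc_sd < threshold``.
    """

    plate_ipc_means: dict[str, float]
    global_mean: float
    factors: dict[str, float]
    ipc_sd: float
    passed: bool
    threshold: float = IPC_SD_THRESHOLD


def ipc_qc(table: CtTable, threshold: float = IPC_SD_THRESHOLD) -> CalibrationReport:
    """Summarize IPC wells per plate and apply the SD quality gate.

    The SD is the sample standard deviation of plate-level IPC means taken
    jointly across all plates of the run; a single-plate run has SD 0 and
    trivially passes.
    """
    ipc_features = table.features_with_role("ipc")
    if not ipc_features:
        raise CalibrationError("table contains no features of role 'ipc'")
    plates_all = sorted(set(table.plates.to_numpy().ravel()))
    wells: dict[str, list[float]] = {p: [] for p in plates_all}
    for f in ipc_features:
        for s in table.samples:
            wells[table.plates.at[f, s]].append(float(table.values.at[f, s]))
    missing = [p for p, v in wells.items() if not v]
    if missing:
        raise CalibrationError(f"plate {missing[0]!r} has no IPC well")
    plate_means = {p: float(np.mean(v)) for p, v in wells.items()}
    means = np.array([plate_means[p] for p in plates_all])
    global_mean = float(means.mean())
    ipc_sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    factors = {p: global_mean - plate_means[p] for p in plates_all}
    passed = ipc_sd < threshold
    logger.info(
        "IPC QC: %d plates, SD of plate means %.4f cycles -> %s",
        len(plates_all), ipc_sd, "pass" if passed else "FAIL",
    )
    return CalibrationReport(
        plate_ipc_means=plate_means,
        global_mean=global_mean,
        factors=factors,
        ipc_sd=ipc_sd,
        passed=passed,
        threshold=threshold,
    )


def calibrate(table: CtTable, report: CalibrationReport, override: bool = False) -> CtTable:
    """Apply the additive per-plate calibration factors.

    Censored wells stay censored at the ceiling.  A well pushed to or past
    the ceiling by calibration becomes censored (logged).  Refuses to run on
    a failed QC report unless ``override`` is set, in which case the override
    is logged loudly.
    """
    if not report.passed:
        if not override:
            raise CalibrationError(
                f"IPC QC failed (SD {report.ipc_sd:.4f} >= {report.threshold}); "
                "pass override=True to calibrate anyway"
            )
        logger.warning(
            "OVERRIDE: calibrating despite failed IPC QC (SD %.4f >= %s)",
            report.ipc_sd, report.threshold,
        )
    cf = table.plates.map(lambda p: report.factors[p]).astype(float)
    values = table.values + cf
    censored = table.censored.copy()
    values = values.where(~censored, table.ceiling)
    newly = (values >= table.ceiling) & ~censored
    n_new = int(newly.to_numpy().sum())
    if n_new:
        logger.warning("calibration pushed %d wells to the ceiling; now censored", n_new)
        values = values.where(~newly, table.ceiling)
        censored = censored | newly
    return CtTable(
        values=values,
        censored=censored,
        roles=table.roles.copy(),
        panels=table.panels.copy(),
        plates=table.plates.copy(),
        ceiling=table.ceiling,
    )


def filter_expressed(
    table: CtTable, panel_policy: str = "panel_I_only", ceiling: float | None = None
) -> CtTable:
    """Keep target features expressed in *all* samples (strictly below the
    ceiling), optionally restricted to panel I; controls are kept unchanged.

    Features touching the ceiling in even one sample are on/off-ambiguous
    and removed — the strict rule that defines the analyzable set.
    """
    if panel_policy not in ("panel_I_only", "all"):
        raise ValueError(f"panel_policy must be 'panel_I_only' or 'all', got {panel_policy!r}")
    ceiling = table.ceiling if ceiling is None else ceiling
    keep: list[str] = []
    for f in table.features:
        if table.roles[f] != "target":
            keep.append(f)
            continue
        if panel_policy == "panel_I_only" and table.panels[f] != "I":
            continue
        row = table.values.loc[f].to_numpy(dtype=float)
        if bool(np.all(row < ceiling)) and not bool(table.censored.loc[f].any()):
            keep.append(f)
    n_targets = sum(1 for f in keep if table.roles[f] == "target")
    if n_targets == 0:
        raise ValidationError("no target feature survives the expression filter")
    logger.info("expression filter: %d target features survive", n_targets)
    return table.subset(keep)
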