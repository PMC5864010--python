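import numpy as np
import pandas as pd
import pytest

from mirserum.containers import CtTable, SampleSheet
from mirserum.simulate import SimConfig, simulate_experiment, target_names


def make_ct_table(values: dict, roles: dict, panels: dict | None = None, plates=None):
    """Small hand-built CtTable: values is {feature: {sample: ct}}."""
    df = pd.DataFrame(values).T.astype(float)
    features, samples = list(df.index), list(df.columns)
    censored = df >= 40.0
    df = df.where(~censored, 40.0)
    panels = panels or {f: "I" for f in features}
    if plates is None:
        plates_df = pd.DataFrame(
            {s: [f"{panels[f]}-{s}" for f in features] for s in samples}, index=features
        )
    else:
        plates_df = pd.DataFrame(plates).T.reindex(index=features, columns=samples)
    return CtTable(
        values=df,
        censored=censored,
        roles=pd.Series(roles).loc[features],
        panels=pd.Series(panels).loc[features],
        plates=plates_df,
    )


def make_sheet(groups: dict):
    """SampleSheet from {sample: group}; replicate index assigned per group."""
    rows, counts = [], {}
    for s, g in groups.items():
        counts[g] = counts.get(g, 0) + 1
        rows.append({"sample": s, "group": g, "replicate": counts[g]})
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def spiked_experiment():
    """One simulated panel run with ten strong spikes in the mild group.

    Spiked assays are chosen among well-expressed features (max Ct < 34) so
    a positive shift cannot push them over the detection ceiling — the same
    consideration a real spike-in design applies.
    """
    base_table, _, _ = simulate_experiment(SimConfig(seed=42))
    wells = [
        f for f in base_table.features
        if base_table.roles[f] == "target" and base_table.panels[f] == "I"
        and float(base_table.values.loc[f].max()) < 34.0
    ]
    deltas = [-4.7, 3.2, -3.6, 4.0, -3.0, 3.3, -5.1, 3.8, -3.2, 4.4]
    spikes = [(f, "mild", d) for f, d in zip(wells[:10], deltas)]
    cfg = SimConfig(seed=42, spikes=spikes)
    table, sheet, truth = simulate_experiment(cfg)
    return cfg, table, sheet, truth


@pytest.fixture(scope="session")
def null_experiment():
    cfg = SimConfig(seed=11)
    table, sheet, truth = simulate_experiment(cfg)
    return cfg, table, sheet, truth
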