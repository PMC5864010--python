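"""Readers and writers for the pipeline's tabular interchange formats.

Canonical dialects (UTF-8, tab- or comma-separated by file extension):

* **Ct table, wide**: one row per feature, columns ``feature, role, panel``
  followed by one column per sample.  A well's plate is implied by its
  (panel, sample) pair — every sample is run once per physical panel plate —
  and named ``{panel}-{sample}``.
* **Ct table, long**: tidy rows ``plate, feature, role, panel, sample, Ct``
  with an explicit plate per well.
* **sample sheet**: CSV/TSV with columns ``sample, group, replicate``.
* **target map**: TSV with columns ``mirna, gene`` (ENTREZ integer) and an
  optional ``evidence`` tag; duplicate pairs are collapsed on load.
* **term map**: TSV whose first line declares the background
  (``#background=<N>``) followed by rows ``term<TAB>comma-separated gene
  ids``; alternatively JSON ``{"background": N, "terms": {...}}``.

Censoring convention: a blank Ct cell, or any value at/above the 40-cycle
ceiling, is read as right-censored and stored as exactly 40.0 with the flag
set.  Any other non-numeric entry is a hard error naming the cell.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CT_CEILING,
    PANELS,
    ROLES,
    CtTable,
    SampleSheet,
    TargetMap,
    TermMap,
    ValidationError,
)
from .names import normalize_mirna_name

logger = logging.getLogger(__name__)

_META_COLS_WIDE = ["feature", "role", "panel"]
_COLS_LONG = ["plate", "feature", "role", "panel", "sample", "Ct"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_ct_cell(raw, feature: str, sample: str, ceiling: float) -> tuple[float, bool]:
    """Return (value, censored) for one raw cell; hard error on junk."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ceiling, True
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "undetermined"}:
        return ceiling, True
    if text.startswith(">"):
        text = text[1:]
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"non-numeric Ct {raw!r} at ({feature!r}, {sample!r})"
        ) from None
    if value >= ceiling:
        return ceiling, True
    return value, False


def read_ct_table(path, layout: str = "wide", ceiling: float = CT_CEILING) -> CtTable:
    """Read a Ct table in the wide or long dialect into a validated CtTable."""
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if layout == "wide":
        missing = [c for c in _META_COLS_WIDE if c not in raw.columns]
        if missing:
            raise ValidationError(f"wide Ct table missing columns {missing}")
        sample_cols = [c for c in raw.columns if c not in _META_COLS_WIDE]
        if not sample_cols:
            raise ValidationError("wide Ct table declares no sample columns")
        rows = []
        for _, r in raw.iterrows():
            feat = normalize_mirna_name(r["feature"])
            for s in sample_cols:
                rows.append((f"{r['panel']}-{s}", feat, r["role"], r["panel"], s, r[s]))
        long = pd.DataFrame(rows, columns=_COLS_LONG)
    else:
        missing = [c for c in _COLS_LONG if c not in raw.columns]
        if missing:
            raise ValidationError(f"long Ct table missing columns {missing}")
        long = raw[_COLS_LONG].copy()
        long["feature"] = long["feature"].map(normalize_mirna_name)

    dup = long.duplicated(subset=["feature", "sample"])
    if dup.any():
        r = long.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate cell for ({r['feature']!r}, {r['sample']!r}) in {path.name}"
        )
    for col, allowed in (("role", ROLES), ("panel", PANELS)):
        bad = set(long[col]) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} token {sorted(bad)[0]!r} in {path.name}")

    features = list(dict.fromkeys(long["feature"]))
    samples = list(dict.fromkeys(long["sample"]))
    values = pd.DataFrame(np.nan, index=features, columns=samples, dtype=float)
    censored = pd.DataFrame(False, index=features, columns=samples)
    plates = pd.DataFrame("", index=features, columns=samples, dtype=object)
    roles = {}
    panels = {}
    for _, r in long.iterrows():
        v, c = _parse_ct_cell(r["Ct"], r["feature"], r["sample"], ceiling)
        values.at[r["feature"], r["sample"]] = v
        censored.at[r["feature"], r["sample"]] = c
        plates.at[r["feature"], r["sample"]] = r["plate"]
        prev = roles.setdefault(r["feature"], r["role"])
        if prev != r["role"]:
            raise ValidationError(f"feature {r['feature']!r} has conflicting roles")
        prev = panels.setdefault(r["feature"], r["panel"])
        if prev != r["panel"]:
            raise ValidationError(f"feature {r['feature']!r} has conflicting panels")
    if values.isna().any().any():
        f = values.index[values.isna().any(axis=1)][0]
        s = values.columns[values.loc[f].isna()][0]
        raise ValidationError(f"missing well for ({f!r}, {s!r}) in {path.name}")

    table = CtTable(
        values=values,
        censored=censored,
        roles=pd.Series(roles).loc[features],
        panels=pd.Series(panels).loc[features],
        plates=plates,
        ceiling=ceiling,
    )
    logger.info(
        "read %d features x %d samples from %s (%d censored wells)",
        len(features), len(samples), path, table.n_censored(),
    )
    return table


def write_ct_table(table: CtTable, path, layout: str = "long") -> None:
    """Write a CtTable in the long (lossless) or wide dialect.

    Censored wells are written blank, so read/write round-trips are exact on
    uncensored tables and preserve the censoring convention otherwise.
    """
    path = Path(path)
    sep = _sep_for(path)

    def fmt(f, s):
        if table.censored.at[f, s]:
            return ""
        v = table.values.at[f, s]
        return format(v, "g")

    if layout == "long":
        rows = [
            {
                "plate": table.plates.at[f, s],
                "feature": f,
                "role": table.roles[f],
                "panel": table.panels[f],
                "sample": s,
                "Ct": fmt(f, s),
            }
            for f in table.features
            for s in table.samples
        ]
        pd.DataFrame(rows, columns=_COLS_LONG).to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        rows = []
        for f in table.features:
            row = {"feature": f, "role": table.roles[f], "panel": table.panels[f]}
            row.update({s: fmt(f, s) for s in table.samples})
            rows.append(row)
        pd.DataFrame(rows, columns=_META_COLS_WIDE + table.samples).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df["sample"] = df["sample"].astype(str)
    df["group"] = df["group"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    path = Path(path)
    sheet.table.to_csv(path, sep=_sep_for(path), index=False)


def read_target_map(path) -> TargetMap:
    """Read a miRNA -> gene interaction TSV, collapsing duplicate pairs."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"mirna", "gene"} <= set(df.columns):
        raise ValidationError(f"{path.name}: target map needs columns 'mirna', 'gene'")
    df["mirna"] = df["mirna"].astype(str).map(normalize_mirna_name)
    df["gene"] = df["gene"].astype(int)
    if (df["gene"] <= 0).any():
        bad = df.loc[df["gene"] <= 0].iloc[0]
        raise ValidationError(
            f"{path.name}: non-positive gene id {bad['gene']} for {bad['mirna']!r}"
        )
    before = len(df)
    df = df.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("target map %s: dropped %d duplicate pairs", path.name, dropped)
    return TargetMap(pairs=df, n_duplicates_dropped=dropped)


def read_term_map(path) -> TermMap:
    """Read a pathway term map (TSV with #background header, or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        blob = json.loads(path.read_text())
        terms = {t: {int(g) for g in gs} for t, gs in blob["terms"].items()}
        return TermMap(terms=terms, background_size=int(blob["background"]))
    background = None
    terms: dict[str, set[int]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition("=")
            if key.strip() == "background":
                background = int(val)
            continue
        term, _, genes = line.partition("\t")
        if not genes:
            raise ValidationError(f"{path.name}: term line without genes: {line[:40]!r}")
        terms[term] = {int(g) for g in genes.replace(",", " ").split()}
    if background is None:
        raise ValidationError(f"{path.name}: missing '#background=<N>' declaration")
    return TermMap(terms=terms, background_size=background)


def write_term_map(tmap: TermMap, path) -> None:
    path = Path(path)
    lines = [f"#background={tmap.background_size}"]
    for term, genes in tmap.terms.items():
        lines.append(term + "\t" + ",".join(str(g) for g in sorted(genes)))
    path.write_text("\n".join(lines) + "\n")
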