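"""Published reference screening tables shipped with the package.

These are the candidate-miRNA result tables of the serum sulfur-mustard
screening study deposited as GEO accession GSE110797 (raw-branch analysis):
the normal-vs-mild list (15 miRNAs) and the normal-vs-severe list (29
miRNAs), each with the group delta-Ct difference, fold change, model p and
sampling p as printed.  They serve as fixed inputs for cross-checking the
package's fold-change arithmetic and candidate-intersection logic against
an external result.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .differential import CandidateSet

_FILES = {
    "mild": "screen_normal_vs_mild.tsv",
    "severe": "screen_normal_vs_severe.tsv",
}


def load_screen_table(comparison: str) -> pd.DataFrame:
    """Load a published screening table ('mild' or 'severe').

    Columns: ``MicroRNA Name, dCt, FC, p value, sampling p``; dCt is the
    case-minus-control delta-Ct difference (positive = down in cases).
    """
    if comparison not in _FILES:
        raise KeyError(f"comparison must be one of {sorted(_FILES)}, got {comparison!r}")
    path = resources.files("mirserum.data") / _FILES[comparison]
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def screen_candidate_set(comparison: str, alpha: float = 0.05) -> CandidateSet:
    """Published screening list as a CandidateSet (direction from FC)."""
    df = load_screen_table(comparison)
    members = [
        (row["MicroRNA Name"], "up" if row["FC"] > 1.0 else "down")
        for _, row in df.iterrows()
    ]
    return CandidateSet(
        comparison=f"normal_vs_{comparison}", branch="raw", members=members, alpha=alpha
    )
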