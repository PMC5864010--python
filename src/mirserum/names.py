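"""miRNA feature-name normalization.

Vendor exports and published tables spell the same assay several ways
(``HSA-MIR-143-3P``, ``hsa-mir-143-3p``, ``miR-143-3p``).  Everything in this
package compares names after :func:`normalize_mirna_name`, which maps them to
the miRBase-style form ``hsa-miR-143-3p`` while preserving arm suffixes and
star annotations (``hsa-miR-30b*-3p``).
"""

from __future__ import annotations

import re

_MIR_RE = re.compile(r"^(?:hsa-)?(mir|miR|let|MIR|LET)-(.+)$", re.IGNORECASE)


def normalize_mirna_name(name: str) -> str:
    """Return the canonical miRBase-style spelling of a miRNA assay name.

    Non-miRNA names (reference snoRNAs, IPC spikes, ``U6``) are returned
    stripped but otherwise unchanged.
    """
    name = name.strip()
    m = _MIR_RE.match(name)
    if m is None:
        return name
    stem = m.group(1).lower()
    rest = m.group(2).lower()
    if stem == "let":
        return f"hsa-let-{rest}"
    return f"hsa-miR-{rest}"


def normalize_names(names) -> list[str]:
    return [normalize_mirna_name(n) for n in names]
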