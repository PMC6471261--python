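"""Per-library miRNA expression and family summaries.

Expression is tags-per-million (TPM): a miRNA's tag count in a library
divided by that library's total clean-tag count (all categories, the
literal denominator) times 10^6.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotate import TagAnnotation
from .preprocess import CleanTag

log = logging.getLogger("mejamir")


def tpm(count: int, total_clean_tags: int) -> float:
    """count / total × 10^6."""
    if total_clean_tags <= 0:
        raise ValueError("total clean-tag count must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean_tags * 1e6


def expression_matrix(
    annotations: list[TagAnnotation],
    tags: list[CleanTag],
    libraries: list[str],
    totals: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """miRNA × library count and TPM matrices, plus a miRNA → family map.

    Rows are known + novel miRNAs.  Each tag contributes its counts to
    exactly one miRNA row; a tag matching several references equally was
    already resolved to the alphabetically first id by the annotator (and
    is logged here when two annotated tags share a miRNA id).
    """
    by_tag = {a.tag_id: a for a in annotations}
    tag_ids = [f"tag{i}" for i in range(1, len(tags) + 1)]
    rows: dict[str, dict[str, int]] = {}
    fams: dict[str, str] = {}
    for tid, tag in zip(tag_ids, tags):
        ann = by_tag.get(tid)
        if ann is None or ann.category not in ("known_mirna", "novel_candidate"):
            continue
        mid = ann.mirna_id
        if mid in rows:
            log.info("quantify: tag %s adds to existing miRNA row %s", tid, mid)
        row = rows.setdefault(mid, {lib: 0 for lib in libraries})
        for lib, c in tag.count_per_library.items():
            row[lib] += c
        fams[mid] = ann.family or mid
    counts = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if counts.empty:
        counts = pd.DataFrame(columns=libraries, dtype=int)
    counts = counts.reindex(columns=libraries, fill_value=0).sort_index()
    denom = np.array([totals[lib] for lib in libraries], dtype=float)
    if (denom <= 0).any():
        raise ValueError("every library needs a positive clean-tag total")
    tpms = counts / denom * 1e6
    families = pd.DataFrame(
        {"family": [fams[m] for m in counts.index]}, index=counts.index
    )
    return counts, tpms, families


def family_abundance(
    counts: pd.DataFrame,
    families: pd.DataFrame,
    sample_of_library: dict[str, str],
) -> pd.DataFrame:
    """Family presence/absence table ranked by total count.

    One row per family, '+'/'−' per timepoint (present iff the family's
    summed count at that timepoint is > 0), sorted by total count
    descending with alphabetical tie-break.
    """
    if counts.empty:
        raise ValueError("expression matrix is empty")
    fam = families["family"]
    total = counts.sum(axis=1).groupby(fam).sum()
    timepoints = sorted(set(sample_of_library.values()),
                        key=list(sample_of_library.values()).index)
    flags = {}
    for tp in timepoints:
        libs = [l for l in counts.columns if sample_of_library[l] == tp]
        present = counts[libs].sum(axis=1).groupby(fam).sum() > 0
        flags[tp] = present.map({True: "+", False: "−"})
    out = pd.DataFrame(flags)
    out["total_count"] = total
    # descending total, alphabetical tie-break (stable sort on sorted index)
    out = out.sort_index().sort_values("total_count", ascending=False, kind="stable")
    return out
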