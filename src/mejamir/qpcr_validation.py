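"""Comparative-Ct (2^−ΔΔCt) relative expression and concordance with
sequencing fold changes.

ΔCt = mean Ct(target) − mean Ct(reference, U6) within a condition;
ΔΔCt = ΔCt(treatment) − ΔCt(control); fold = 2^−ΔΔCt.  The replicate
spread is carried as the SD of per-replicate ΔCt values in the treatment
condition, reported on the fold scale as the 2^−(ΔΔCt±SD) range.
Concordance with the pipeline is assessed on direction only (up/down
versus the control), since qPCR and sequencing magnitudes are not on a
common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REFERENCE_ASSAY = "U6"


@dataclass
class CtRecord:
    sample: str
    timepoint: str
    assay: str
    ct: list[float]

    def __post_init__(self) -> None:
        if not self.ct:
            raise ValueError("at least one Ct replicate required")
        if any(not 0 < c < 45 for c in self.ct):
            raise ValueError(f"Ct out of range (0, 45) for {self.assay}/{self.timepoint}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.ct))


@dataclass
class RelExpression:
    mirna: str
    timepoint: str
    fold: float
    sd: float           # SD of treatment replicate ΔCt values
    fold_low: float     # 2^−(ΔΔCt+SD)
    fold_high: float    # 2^−(ΔΔCt−SD)


def ddct(
    target: CtRecord,
    reference: CtRecord,
    control_target: CtRecord,
    control_reference: CtRecord,
) -> RelExpression:
    """2^−ΔΔCt of `target` (vs its U6 reference) relative to the control
    condition.  Raises if the reference assay records are missing/wrong."""
    for ref in (reference, control_reference):
        if ref is None:
            raise ValueError("reference (U6) record missing")
        if ref.assay != REFERENCE_ASSAY:
            raise ValueError(f"reference assay must be {REFERENCE_ASSAY}, got {ref.assay}")
    dct_treat = target.mean - reference.mean
    dct_ctrl = control_target.mean - control_reference.mean
    ddct_val = dct_treat - dct_ctrl
    # replicate ΔCt spread in the treatment condition
    k = min(len(target.ct), len(reference.ct))
    rep_dct = np.array(target.ct[:k]) - np.array(reference.ct[:k])
    sd = float(np.std(rep_dct, ddof=1)) if k > 1 else 0.0
    return RelExpression(
        mirna=target.assay,
        timepoint=target.timepoint,
        fold=float(2.0 ** -ddct_val),
        sd=sd,
        fold_low=float(2.0 ** -(ddct_val + sd)),
        fold_high=float(2.0 ** -(ddct_val - sd)),
    )


def read_ct_table(path) -> list[CtRecord]:
    """TSV with columns sample, timepoint, assay, ct1..ct3."""
    df = pd.read_csv(path, sep="\t")
    records = []
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    for _, row in df.iterrows():
        cts = [float(row[c]) for c in ct_cols if pd.notna(row[c])]
        records.append(CtRecord(str(row["sample"]), str(row["timepoint"]),
                                str(row["assay"]), cts))
    return records


def relative_expression(
    records: list[CtRecord], control_timepoint: str = "CK"
) -> list[RelExpression]:
    """All per-miRNA per-treatment 2^−ΔΔCt folds from a Ct table."""
    by_key = {(r.timepoint, r.assay): r for r in records}
    assays = sorted({r.assay for r in records if r.assay != REFERENCE_ASSAY})
    timepoints = sorted({r.timepoint for r in records if r.timepoint != control_timepoint})
    out = []
    for assay in assays:
        ctrl_t = by_key.get((control_timepoint, assay))
        ctrl_r = by_key.get((control_timepoint, REFERENCE_ASSAY))
        if ctrl_t is None or ctrl_r is None:
            raise ValueError(f"missing control records for {assay}")
        for tp in timepoints:
            t = by_key.get((tp, assay))
            ref = by_key.get((tp, REFERENCE_ASSAY))
            if t is None:
                continue
            if ref is None:
                raise ValueError(f"missing {REFERENCE_ASSAY} record at {tp}")
            out.append(ddct(t, ref, ctrl_t, ctrl_r))
    return out


def concordance(
    qpcr: list[RelExpression],
    pipeline_log2fc: dict[tuple[str, str], float],
) -> pd.DataFrame:
    """Direction agreement per (miRNA, timepoint); raises on an empty
    intersection.  fold > 1 agrees with log2FC > 0."""
    rows = []
    for rel in qpcr:
        key = (rel.mirna, rel.timepoint)
        if key not in pipeline_log2fc:
            continue
        lfc = pipeline_log2fc[key]
        rows.append({
            "mirna": rel.mirna, "timepoint": rel.timepoint,
            "qpcr_fold": rel.fold, "pipeline_log2fc": lfc,
            "concordant": bool((rel.fold > 1.0) == (lfc > 0.0)),
        })
    if not rows:
        raise ValueError("no shared (miRNA, timepoint) between qPCR and pipeline")
    df = pd.DataFrame(rows)
    df.attrs["fraction_concordant"] = float(df["concordant"].mean())
    return df
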