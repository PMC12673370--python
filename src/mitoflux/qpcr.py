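"""Relative gene expression by the ddCt method.

For each sample, dCt = Ct_target - Ct_reference removes loading/run offsets;
ddCt = dCt - mean(dCt over the control group) references expression to the
control condition; fold change = 2^(-ddCt). No amplification-efficiency
correction is applied (plain 2^-ddCt). The default reference gene is Actb and
the default targets are the mitochondrial-dynamics panel Mfn1, Mfn2, Opa1,
Drp1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_REFERENCE = "Actb"
DEFAULT_TARGETS = ("Mfn1", "Mfn2", "Opa1", "Drp1")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["ct"].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    *,
    reference_gene: str = DEFAULT_REFERENCE,
    control_group: str = "Ctrl",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fold changes and per-group summaries.

    Returns ``(per_sample, per_group)``. Samples without a reference-gene Ct
    are dropped with a warning; an empty control group for any gene is an
    error. The control baseline is the arithmetic mean of control dCt.
    Per-group fold changes are summarized as mean +/- SD.
    """
    table = _validate(table.copy())
    ref = table[table["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = table[table["gene"] != reference_gene].copy()
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")

    has_ref = targets["sample_id"].isin(ref.index)
    if not has_ref.all():
        dropped = sorted(targets.loc[~has_ref, "sample_id"].unique())
        warnings.warn(f"samples without reference-gene Ct dropped: {dropped}")
        targets = targets[has_ref]

    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "dct"]
        if ctrl.empty:
            raise ValueError(f"control group {control_group!r} empty for gene {gene!r}")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - ctrl.mean()
        sub["fold_change"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    per_sample = pd.concat(out, ignore_index=True)

    per_group = (
        per_sample.groupby(["gene", "group"], sort=False)["fold_change"]
        .agg(mean_fold="mean", sd_fold="std", n="count")
        .reset_index()
    )
    return per_sample, per_group


def reference_stability(
    table: pd.DataFrame, *, reference_gene: str = DEFAULT_REFERENCE
) -> pd.DataFrame:
    """Per-group mean +/- SD of the reference-gene Ct (housekeeping check).

    Single-sample groups report a missing SD.
    """
    table = _validate(table.copy())
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    return (
        ref.groupby("group", sort=False)["ct"]
        .agg(mean_ct="mean", sd_ct="std", n="count")
        .reset_index()
    )
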