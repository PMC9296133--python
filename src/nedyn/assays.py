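"""Tabular assay calculations: embryonic lethality and qPCR fold change.

Lethality: per worm, hatched larvae and unhatched embryos are counted in
scoring windows (24-48 h and 48-72 h); windows are pooled per worm, so
lethality = unhatched / (hatched + unhatched) and brood size is the total.

qPCR: relative expression by the 2^(-ddCt) method.  Technical replicates are
averaged per sample first, dCt = Ct_target - Ct_reference per sample,
ddCt = dCt - mean control dCt per gene, fold change = 2^(-ddCt).  The
reference gene is a required argument — it is never defaulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class LethalitySummary:
    per_worm: pd.DataFrame
    per_condition: pd.DataFrame
    n_excluded: int


def lethality(records: pd.DataFrame,
              condition_col: str = "condition") -> LethalitySummary:
    """Per-worm and per-condition embryonic lethality and brood size.

    ``records`` needs columns worm_id, hatched, unhatched and optionally a
    condition column and a window column (windows are summed per worm).
    Worms with zero scored embryos are excluded with a warning.
    """
    df = records.copy()
    for col in ("worm_id", "hatched", "unhatched"):
        if col not in df.columns:
            raise InputError(f"missing column {col!r}")
    if condition_col not in df.columns:
        df[condition_col] = "all"
    counts = df[["hatched", "unhatched"]].to_numpy()
    if not np.all(np.isfinite(counts)) or (counts < 0).any() \
            or not np.all(counts == np.round(counts)):
        raise InputError("hatched/unhatched must be non-negative integers")

    per_worm = (df.groupby([condition_col, "worm_id"], sort=True)
                [["hatched", "unhatched"]].sum().reset_index())
    per_worm["brood_size"] = per_worm["hatched"] + per_worm["unhatched"]
    zero = per_worm["brood_size"] == 0
    n_excluded = int(zero.sum())
    if n_excluded:
        excluded = per_worm.loc[zero, "worm_id"].tolist()
        warnings.warn(f"excluding worms with zero scored embryos: {excluded}",
                      stacklevel=2)
        per_worm = per_worm[~zero].reset_index(drop=True)
    if per_worm.empty:
        raise InputError("no worm with a non-zero brood")
    per_worm["lethality_pct"] = (100.0 * per_worm["unhatched"]
                                 / per_worm["brood_size"])

    grouped = per_worm.groupby(condition_col, sort=True)
    per_condition = grouped.agg(
        n_worms=("worm_id", "size"),
        n_embryos=("brood_size", "sum"),
        mean_lethality_pct=("lethality_pct", "mean"),
        sd_lethality_pct=("lethality_pct", lambda s: s.std(ddof=1)),
        min_lethality_pct=("lethality_pct", "min"),
        max_lethality_pct=("lethality_pct", "max"),
        mean_brood_size=("brood_size", "mean"),
    ).reset_index()
    return LethalitySummary(per_worm=per_worm, per_condition=per_condition,
                            n_excluded=n_excluded)


@dataclass
class DdCtResult:
    per_sample: pd.DataFrame   # sample-level dCt, ddCt, fold change
    summary: pd.DataFrame      # per gene x condition mean +/- sd fold change
    reference_gene: str
    control: str


def ddct(ct_table: pd.DataFrame, control: str, reference_gene: str,
         geometric: bool = False) -> DdCtResult:
    """Relative expression by 2^(-ddCt) for every target gene x condition.

    ``ct_table`` needs columns sample, condition, gene, Ct.  Rows sharing
    (sample, condition, gene) are technical replicates and are averaged
    before any difference is taken.  Samples lacking the reference gene are
    dropped with a warning.  Fold changes are summarized over biological
    replicates with the arithmetic mean by default (``geometric=True``
    switches to the geometric mean, i.e. the mean on the ddCt scale).
    """
    for col in ("sample", "condition", "gene", "Ct"):
        if col not in ct_table.columns:
            raise InputError(f"missing column {col!r}")
    df = ct_table.copy()
    if not df["condition"].eq(control).any():
        raise InputError(f"control condition {control!r} not present")
    if not df["gene"].eq(reference_gene).any():
        raise InputError(f"reference gene {reference_gene!r} not present")

    # technical replicates -> one Ct per (sample, condition, gene)
    mean_ct = (df.groupby(["sample", "condition", "gene"], sort=True)["Ct"]
               .mean().reset_index())
    ref = (mean_ct[mean_ct["gene"] == reference_gene]
           .rename(columns={"Ct": "Ct_ref"})[["sample", "condition", "Ct_ref"]])
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    merged = targets.merge(ref, on=["sample", "condition"], how="left")
    dropped = merged[merged["Ct_ref"].isna()]["sample"].unique().tolist()
    if dropped:
        warnings.warn(f"samples missing reference Ct dropped: {dropped}",
                      stacklevel=2)
        merged = merged.dropna(subset=["Ct_ref"])
    if merged.empty:
        raise InputError("no sample has both target and reference Ct")
    merged["dCt"] = merged["Ct"] - merged["Ct_ref"]

    control_dct = (merged[merged["condition"] == control]
                   .groupby("gene")["dCt"].mean()
                   .rename("control_dCt").reset_index())
    merged = merged.merge(control_dct, on="gene", how="inner")
    merged["ddCt"] = merged["dCt"] - merged["control_dCt"]
    merged["fold_change"] = 2.0 ** (-merged["ddCt"])

    if geometric:
        summary = (merged.groupby(["gene", "condition"], sort=True)
                   .agg(n=("sample", "size"),
                        mean_fold=("ddCt", lambda s: 2.0 ** (-s.mean())),
                        sd_fold=("fold_change",
                                 lambda s: s.std(ddof=1) if len(s) > 1
                                 else np.nan))
                   .reset_index())
    else:
        summary = (merged.groupby(["gene", "condition"], sort=True)
                   .agg(n=("sample", "size"),
                        mean_fold=("fold_change", "mean"),
                        sd_fold=("fold_change",
                                 lambda s: s.std(ddof=1) if len(s) > 1
                                 else np.nan))
                   .reset_index())
    per_sample = merged[["sample", "condition", "gene", "Ct", "Ct_ref",
                         "dCt", "ddCt", "fold_change"]]
    return DdCtResult(per_sample=per_sample, summary=summary,
                      reference_gene=reference_gene, control=control)
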