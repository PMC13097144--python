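"""Screen triage: hit calls, toxicity and autofluorescence flags, ROC.

All operations act on tidy per-well summary frames (one row per well, as
produced by :func:`foxscreen.gating.summarize_plate`) so they can be driven
equally from simulations, segmented streams, or externally exported tables.

Statistics follow the screen's conventions:

* hit calls: FoxP3%-of-CD4 fold change vs. the plate DMSO mean, +-50%;
* toxicity: FSC-H delta-ratio (compound lymphocyte median over the pooled
  plate DMSO median) z-scored over compound wells, |z| >= 3;
* autofluorescence: FoxP3+/FoxP3- V450 median ratio z-scored per plate,
  |z| >= 3 -> high, z <= -1 -> low/moderate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import EventTable

__all__ = [
    "RocCurve",
    "call_hits",
    "delta_ratio",
    "toxicity_outliers",
    "v450_stain_ratio",
    "autofluorescence_flags",
    "channel_interference_profile",
    "roc_analysis",
    "normalize_viability",
    "compile_triage_report",
]


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------


def call_hits(per_well: pd.DataFrame, fold_threshold: float = 0.5) -> pd.DataFrame:
    """Fold change vs. the plate DMSO-positive mean and the +-50% rule.

    Adds ``foxp3_fold`` and ``hit_call`` (up | down | none) columns for
    compound wells: up iff fold >= 1 + fold_threshold, down iff
    fold <= 1 - fold_threshold.
    """
    if not 0 < fold_threshold < 1:
        raise ValueError("fold_threshold must be in (0, 1)")
    out = per_well.copy()
    out["foxp3_fold"] = np.nan
    out["hit_call"] = ""
    for plate_id, grp in out.groupby("plate_id"):
        dmso = grp.loc[grp["role"] == "dmso_positive", "foxp3_pct_cd4"]
        if dmso.empty:
            raise ValueError(f"plate {plate_id!r} has no dmso_positive wells")
        mean = float(dmso.mean())
        if mean == 0 or np.isnan(mean):
            raise ValueError(f"plate {plate_id!r}: DMSO mean FoxP3% is zero or NaN")
        idx = grp.index[grp["role"] == "compound"]
        fold = out.loc[idx, "foxp3_pct_cd4"].to_numpy(float) / mean
        out.loc[idx, "foxp3_fold"] = fold
        call = np.where(fold >= 1 + fold_threshold, "up", np.where(fold <= 1 - fold_threshold, "down", "none"))
        out.loc[idx, "hit_call"] = call
    return out


# ---------------------------------------------------------------------------
# Toxicity
# ---------------------------------------------------------------------------


def delta_ratio(per_well: pd.DataFrame, dmso_fsch_by_plate: dict[str, float]) -> pd.DataFrame:
    """FSC-H delta-ratio: each well's lymphocyte FSC-H median divided by the
    FSC-H median of events pooled across the plate's DMSO wells."""
    out = per_well.copy()
    ratios = np.full(len(out), np.nan)
    for i, (plate_id, fsch) in enumerate(zip(out["plate_id"], out["fsch_mfi"])):
        ref = dmso_fsch_by_plate.get(plate_id, np.nan)
        if np.isnan(ref):
            raise ValueError(f"no pooled DMSO FSC-H reference for plate {plate_id!r}")
        if ref == 0:
            raise ValueError(f"plate {plate_id!r}: pooled DMSO FSC-H median is zero")
        ratios[i] = fsch / ref
    out["delta_ratio"] = ratios
    return out


def toxicity_outliers(
    per_well: pd.DataFrame,
    scope: str = "screen",
    k: float = 3.0,
    *,
    min_wells: int = 10,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Z-score the delta-ratio over compound wells and flag outliers.

    ``scope='screen'`` pools every compound well; ``scope='plate'`` computes
    mean/SD per plate.  Control wells are excluded from the statistics and
    never flagged.
    """
    if scope not in ("screen", "plate"):
        raise ValueError("scope must be 'screen' or 'plate'")
    out = per_well.copy()
    out["tox_z"] = np.nan
    out["toxic"] = False
    is_compound = out["role"] == "compound"

    def flag(idx) -> None:
        vals = out.loc[idx, "delta_ratio"].to_numpy(float)
        if len(vals) < min_wells:
            raise ValueError(f"need at least {min_wells} compound wells in scope, got {len(vals)}")
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValueError("delta-ratio SD is zero; cannot z-score")
        z = (vals - float(np.mean(vals))) / sd
        out.loc[idx, "tox_z"] = z
        out.loc[idx, "toxic"] = (np.abs(z) if two_sided else -z) >= k

    if scope == "screen":
        flag(out.index[is_compound])
    else:
        for _, grp in out.groupby("plate_id"):
            flag(grp.index[grp["role"] == "compound"])
    return out


def normalize_viability(live_pct_compound: float, live_pct_dmso: float) -> float:
    """Percent-of-DMSO viability."""
    if live_pct_dmso <= 0:
        raise ValueError("DMSO live% must be positive")
    return 100.0 * live_pct_compound / live_pct_dmso


# ---------------------------------------------------------------------------
# Autofluorescence
# ---------------------------------------------------------------------------


def v450_stain_ratio(per_well: pd.DataFrame, *, min_events: int = 10) -> pd.DataFrame:
    """Per-well stain ratio: V450 median of FoxP3+ over V450 median of FoxP3-.

    Wells whose FoxP3- median is <= 0 (possible after compensation) or whose
    populations fall below ``min_events`` are marked indeterminate (NaN
    ratio).
    """
    out = per_well.copy()
    pos = out["v450_mfi_pos"].to_numpy(float)
    neg = out["v450_mfi_neg"].to_numpy(float)
    n_pos = out["n_foxp3_pos"].to_numpy(float) if "n_foxp3_pos" in out else np.full(len(out), np.inf)
    n_neg = out["n_foxp3_neg"].to_numpy(float) if "n_foxp3_neg" in out else np.full(len(out), np.inf)
    bad = (neg <= 0) | ~np.isfinite(neg) | ~np.isfinite(pos) | (n_pos < min_events) | (n_neg < min_events)
    ratio = np.full(len(out), np.nan)
    np.divide(pos, neg, out=ratio, where=~bad)
    out["v450_ratio"] = ratio
    out["v450_ratio_indeterminate"] = bad
    return out


def autofluorescence_flags(
    per_well: pd.DataFrame,
    k_high: float = 3.0,
    k_low: float = 1.0,
    *,
    min_wells: int = 10,
) -> pd.DataFrame:
    """Per-plate z-scores of the V450 stain ratio over compound wells.

    ``high``: |z| >= k_high (either direction — strong shifts can inflate or
    collapse the ratio); ``low_moderate``: z <= -k_low but below the high
    cut; otherwise ``none``.  Indeterminate ratios are flagged high (a FoxP3-
    population erased by a whole-population shift is the extreme case).
    """
    out = per_well.copy()
    out["af_z"] = np.nan
    out["autofluor_level"] = ""
    for plate_id, grp in out.groupby("plate_id"):
        idx = grp.index[grp["role"] == "compound"]
        vals = out.loc[idx, "v450_ratio"].to_numpy(float)
        finite = np.isfinite(vals)
        if finite.sum() < min_wells:
            raise ValueError(
                f"plate {plate_id!r}: need at least {min_wells} determinate compound wells"
            )
        sd = float(np.std(vals[finite], ddof=1))
        if sd == 0:
            raise ValueError(f"plate {plate_id!r}: stain-ratio SD is zero")
        mean = float(np.mean(vals[finite]))
        z = (vals - mean) / sd
        level = np.full(len(vals), "none", dtype=object)
        level[np.abs(z) >= k_high] = "high"
        level[(z <= -k_low) & (np.abs(z) < k_high)] = "low_moderate"
        level[~finite] = "high"
        out.loc[idx, "af_z"] = z
        out.loc[idx, "autofluor_level"] = level
    return out


def channel_interference_profile(
    compound_unstained: EventTable,
    dmso_unstained: EventTable,
    *,
    fold_threshold: float = 2.0,
    fluor_channels: list[str] | None = None,
) -> pd.DataFrame:
    """All-channels-open comparison of an unstained compound well vs DMSO.

    Reports the per-channel median fold change (compound / DMSO) and flags
    channels beyond ``fold_threshold`` (in either direction) as interfered;
    the complement is the safe-channel list for panel redesign.
    """
    if fluor_channels is None:
        fluor_channels = [
            c for c in compound_unstained.channels
            if not c.startswith(("FSC", "SSC", "Time"))
        ]
    shared = [c for c in fluor_channels if c in dmso_unstained.channels]
    if not shared:
        raise ValueError("no shared fluorescence channels to compare")
    missing = set(fluor_channels) - set(shared)
    if missing:
        raise ValueError(f"channels missing from DMSO table: {sorted(missing)}")
    rows = []
    for c in shared:
        ref = float(np.median(dmso_unstained[c]))
        med = float(np.median(compound_unstained[c]))
        if ref <= 0:
            fold = np.inf if med > 0 else np.nan
        else:
            fold = med / ref
        interfered = bool(np.isfinite(fold) and (fold >= fold_threshold or fold <= 1.0 / fold_threshold)) or not np.isfinite(fold)
        rows.append({"channel": c, "median_fold_change": fold, "interfered": interfered})
    df = pd.DataFrame(rows)
    df.attrs["safe_channels"] = df.loc[~df["interfered"], "channel"].tolist()
    return df


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr})


def roc_analysis(scores, labels) -> RocCurve:
    """Threshold-sweep ROC (score >= threshold -> predicted positive), ties
    grouped, AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    cut_idx = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y)[cut_idx]
    fp = np.cumsum(~y)[cut_idx]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[cut_idx]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def compile_triage_report(per_well: pd.DataFrame) -> pd.DataFrame:
    """One row per compound with its hit, toxicity and autofluorescence calls.

    ``candidate``: hits that are neither toxic nor high-autofluorescent.
    Down-hits that are high-autofluorescent (but not toxic) are kept with a
    ``retest_alternate_fluorochrome`` flag rather than silently dropped.
    """
    required = {"hit_call", "toxic", "autofluor_level"}
    missing = required - set(per_well.columns)
    if missing:
        raise ValueError(f"triage report needs columns {sorted(missing)}; run the earlier stages")
    compounds = per_well[per_well["role"] == "compound"].copy()
    if compounds.empty:
        cols = [
            "compound_id", "plate_id", "well", "foxp3_pct_cd4", "foxp3_fold", "hit_call",
            "delta_ratio", "tox_z", "toxic", "v450_ratio", "af_z", "autofluor_level",
            "candidate", "retest_alternate_fluorochrome",
        ]
        return pd.DataFrame(columns=cols)
    is_hit = compounds["hit_call"].isin(["up", "down"])
    af_high = compounds["autofluor_level"] == "high"
    compounds["candidate"] = is_hit & ~compounds["toxic"] & ~af_high
    compounds["retest_alternate_fluorochrome"] = (
        (compounds["hit_call"] == "down") & af_high & ~compounds["toxic"]
    )
    cols = [
        "compound_id", "plate_id", "well", "foxp3_pct_cd4", "foxp3_fold", "hit_call",
        "delta_ratio", "tox_z", "toxic", "v450_ratio", "af_z", "autofluor_level",
        "candidate", "retest_alternate_fluorochrome",
    ]
    present = [c for c in cols if c in compounds.columns]
    return compounds[present].reset_index(drop=True)
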