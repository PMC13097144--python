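"""Z'-factor plate quality control.

Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n| over the FoxP3%-in-CD4
readout of DMSO-stained positive controls and CD4-only negative controls;
plates pass at Z' >= threshold (default 0.5, boundary inclusive).  SDs are
sample SDs (n - 1), appropriate for the small control counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ControlSummary", "PlateQCReport", "zprime_factor", "control_summary", "plate_qc_report"]


@dataclass
class ControlSummary:
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    n_p: int
    n_n: int

    def __post_init__(self) -> None:
        if self.n_p < 2 or self.n_n < 2:
            raise ValueError("need at least 2 wells per control group")
        if self.sigma_p < 0 or self.sigma_n < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class PlateQCReport:
    plate_id: str
    zprime: float
    passed: bool
    threshold: float
    controls: ControlSummary

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "zprime": self.zprime,
            "pass": self.passed,
            "threshold": self.threshold,
            "mu_p": self.controls.mu_p,
            "sigma_p": self.controls.sigma_p,
            "mu_n": self.controls.mu_n,
            "sigma_n": self.controls.sigma_n,
            "n_pos": self.controls.n_p,
            "n_neg": self.controls.n_n,
        }


def zprime_factor(controls: ControlSummary) -> float:
    if controls.mu_p == controls.mu_n:
        raise ValueError("Z'-factor undefined: control means are equal")
    return 1.0 - 3.0 * (controls.sigma_p + controls.sigma_n) / abs(controls.mu_p - controls.mu_n)


def control_summary(per_well: pd.DataFrame, readout: str = "foxp3_pct_cd4") -> ControlSummary:
    """Summarize control wells from a per-well summary frame (needs ``role``
    and the readout column)."""
    for role in ("dmso_positive", "cd4_only_negative"):
        n = int((per_well["role"] == role).sum())
        if n < 2:
            raise ValueError(f"insufficient control wells for role {role!r} (found {n}, need >= 2)")
    pos = per_well.loc[per_well["role"] == "dmso_positive", readout].to_numpy(float)
    neg = per_well.loc[per_well["role"] == "cd4_only_negative", readout].to_numpy(float)
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise ValueError("control wells carry NaN readouts")
    return ControlSummary(
        mu_p=float(np.mean(pos)),
        sigma_p=float(np.std(pos, ddof=1)),
        mu_n=float(np.mean(neg)),
        sigma_n=float(np.std(neg, ddof=1)),
        n_p=len(pos),
        n_n=len(neg),
    )


def plate_qc_report(
    per_well: pd.DataFrame,
    plate_id: str | None = None,
    threshold: float = 0.5,
    readout: str = "foxp3_pct_cd4",
) -> PlateQCReport:
    controls = control_summary(per_well, readout=readout)
    z = zprime_factor(controls)
    if plate_id is None:
        plate_id = str(per_well["plate_id"].iloc[0]) if "plate_id" in per_well.columns else ""
    return PlateQCReport(
        plate_id=plate_id,
        zprime=z,
        passed=bool(z >= threshold),
        threshold=threshold,
        controls=controls,
    )
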