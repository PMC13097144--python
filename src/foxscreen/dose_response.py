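"""Dose-response normalization and log(inhibitor)-vs-response IC50 fitting.

The model is the four-parameter logistic on a log10 dose axis::

    response(d) = bottom + (top - bottom) / (1 + 10 ** ((log10(d) - log10(ic50)) * hill))

so with ``hill > 0`` the curve falls from ``top`` (dose -> 0) to ``bottom``
(dose -> inf) and passes the midpoint at ``d = ic50``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseSeries",
    "FourPLFit",
    "ProliferationResult",
    "four_pl",
    "normalize_response",
    "fit_log_inhibitor",
    "proliferation_readout",
]


def four_pl(dose, ic50: float, hill: float, top: float, bottom: float):
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(dose) - np.log10(ic50)) * hill))


@dataclass
class DoseResponseSeries:
    """Normalized responses (%) observed at positive doses (uM)."""

    compound_id: str
    doses: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have the same shape")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.doses.shape:
                raise ValueError("replicate ids must match observations")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses).size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound_id: str) -> "DoseResponseSeries":
        sub = df[df["compound_id"] == compound_id]
        if sub.empty:
            raise ValueError(f"no rows for compound {compound_id!r}")
        return cls(
            compound_id=compound_id,
            doses=sub["dose_um"].to_numpy(float),
            responses=sub["response_pct"].to_numpy(float),
            replicates=sub["replicate"].to_numpy() if "replicate" in sub.columns else None,
        )


@dataclass
class FourPLFit:
    compound_id: str
    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    model: str = "variable_slope"
    message: str = ""
    ci_ic50: tuple[float, float] | None = None

    def predict(self, dose):
        return four_pl(dose, self.ic50, self.hill, self.top, self.bottom)

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "ic50_um": self.ic50,
            "hill": self.hill,
            "top": self.top,
            "bottom": self.bottom,
            "rss": self.rss,
            "converged": self.converged,
            "model": self.model,
        }


def normalize_response(value: float, dmso_value: float) -> float:
    """Percent-of-DMSO normalization (DMSO set to 100%)."""
    if dmso_value <= 0:
        raise ValueError("DMSO reference must be positive")
    return 100.0 * value / dmso_value


@dataclass
class ProliferationResult:
    condition: str
    pct_proliferated: float
    normalized_to_teff_only: float


def proliferation_readout(
    celltrace_pos_pct: float, teff_only_reference: float, condition: str = ""
) -> ProliferationResult:
    """Normalize a proliferation readout (% dye-positive of live) to the
    responder-only control."""
    if not 0.0 <= celltrace_pos_pct <= 100.0:
        raise ValueError("percentage must be in [0, 100]")
    if teff_only_reference <= 0:
        raise ValueError("reference must be positive")
    return ProliferationResult(
        condition=condition,
        pct_proliferated=celltrace_pos_pct,
        normalized_to_teff_only=100.0 * celltrace_pos_pct / teff_only_reference,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_BOUND_LO = 0.0
_BOUND_HI = 120.0


def _multistart_guesses(xc: np.ndarray, y: np.ndarray, model: str) -> list[np.ndarray]:
    """Initial parameter vectors from data quantiles (in centered log-dose)."""
    q25, q50, q75 = np.quantile(xc, [0.25, 0.5, 0.75])
    top0 = float(np.clip(np.max(y), _BOUND_LO + 1e-6, _BOUND_HI - 1e-6))
    bot0 = float(np.clip(np.min(y), _BOUND_LO + 1e-6, _BOUND_HI - 1e-6))
    if model == "fixed_asymptotes":
        return [
            np.array([q50, 1.0]),
            np.array([q25, 1.0]),
            np.array([q75, 1.0]),
            np.array([q50, 0.5]),
            np.array([q50, 3.0]),
        ]
    return [
        np.array([q50, 1.0, top0, bot0]),
        np.array([q25, 1.0, top0, bot0]),
        np.array([q75, 1.0, top0, bot0]),
        np.array([q50, 0.5, top0, bot0]),
        np.array([q50, 3.0, top0, bot0]),
    ]


def fit_log_inhibitor(
    series: DoseResponseSeries,
    model: str = "variable_slope",
    *,
    profile_ci: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit on the log10-dose axis with multi-start.

    ``variable_slope`` frees all four parameters with asymptotes bounded to
    [0, 120] %; ``fixed_asymptotes`` pins top=100, bottom=0.  Internally the
    midpoint is parameterized as an offset from the mean log-dose, so rescaling
    every dose by a constant rescales the recovered IC50 by exactly that
    constant.  A flat series is reported as non-converged with no IC50.
    """
    if model not in ("variable_slope", "fixed_asymptotes"):
        raise ValueError(f"unknown model {model!r}")
    if series.n_distinct_doses < 4:
        raise ValueError("need at least 4 distinct doses to fit")
    y = series.responses
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    x = np.log10(series.doses)
    x_center = float(np.mean(x))
    xc = x - x_center

    flat = float(np.ptp(y)) < 1e-9
    if flat:
        return FourPLFit(
            compound_id=series.compound_id,
            ic50=float("nan"),
            hill=float("nan"),
            top=float(np.mean(y)),
            bottom=float(np.mean(y)),
            rss=0.0,
            converged=False,
            model=model,
            message="flat response series; IC50 indeterminate",
        )

    if model == "fixed_asymptotes":

        def residuals(theta):
            delta, hill = theta
            pred = 0.0 + 100.0 / (1.0 + 10.0 ** ((xc - delta) * hill))
            return pred - y

        lb = np.array([-np.inf, -50.0])
        ub = np.array([np.inf, 50.0])
    else:

        def residuals(theta):
            delta, hill, top, bottom = theta
            pred = bottom + (top - bottom) / (1.0 + 10.0 ** ((xc - delta) * hill))
            return pred - y

        lb = np.array([-np.inf, -50.0, _BOUND_LO, _BOUND_LO])
        ub = np.array([np.inf, 50.0, _BOUND_HI, _BOUND_HI])

    best = None
    for theta0 in _multistart_guesses(xc, y, model):
        theta0 = np.clip(theta0, lb + 1e-9, ub - 1e-9)
        try:
            res = least_squares(
                residuals, theta0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(2.0 * res.cost)
        cand_ic50 = 10.0 ** (res.x[0] + x_center)
        if best is None or rss < best[0] - 1e-12 or (
            abs(rss - best[0]) <= 1e-12 and cand_ic50 < best[1]
        ):
            best = (rss, cand_ic50, res)
    if best is None:
        return FourPLFit(
            compound_id=series.compound_id,
            ic50=float("nan"), hill=float("nan"),
            top=float("nan"), bottom=float("nan"),
            rss=float("inf"), converged=False, model=model,
            message="optimizer failed for all starts",
        )
    rss, ic50, res = best
    if model == "fixed_asymptotes":
        delta, hill = res.x
        top, bottom = 100.0, 0.0
    else:
        delta, hill, top, bottom = res.x
    degenerate = abs(top - bottom) < 1e-3 or abs(hill) < 1e-8
    converged = bool(res.success) and not degenerate
    fit = FourPLFit(
        compound_id=series.compound_id,
        ic50=float(ic50) if converged else float("nan"),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        converged=converged,
        model=model,
        message="" if converged else "degenerate fit; IC50 indeterminate",
    )
    if profile_ci and converged:
        fit.ci_ic50 = _profile_ic50_ci(residuals, res.x, rss, x_center, len(y), model)
    return fit


def _profile_ic50_ci(residuals, theta_hat, rss_min, x_center, n, model, level=0.95):
    """Profile-likelihood CI for IC50 via an F-test threshold on the RSS."""
    from scipy.stats import f as f_dist

    p = len(theta_hat)
    if n <= p:
        return None
    fcrit = f_dist.ppf(level, 1, n - p)
    rss_limit = rss_min * (1.0 + fcrit / (n - p))

    def profile_rss(delta_fixed):
        if p == 2:

            def sub(theta):
                return residuals(np.array([delta_fixed, theta[0]]))

            theta0 = theta_hat[1:]
            lb, ub = np.array([-50.0]), np.array([50.0])
        else:

            def sub(theta):
                return residuals(np.concatenate([[delta_fixed], theta]))

            theta0 = theta_hat[1:]
            lb = np.array([-50.0, _BOUND_LO, _BOUND_LO])
            ub = np.array([50.0, _BOUND_HI, _BOUND_HI])
        res = least_squares(sub, np.clip(theta0, lb + 1e-9, ub - 1e-9), bounds=(lb, ub))
        return 2.0 * res.cost

    delta_hat = theta_hat[0]
    grid = delta_hat + np.linspace(-2.0, 2.0, 81)
    inside = np.array([profile_rss(d) <= rss_limit for d in grid])
    if not inside.any():
        return None
    lo = grid[inside][0]
    hi = grid[inside][-1]
    return (10.0 ** (lo + x_center), 10.0 ** (hi + x_center))


def fit_frame(df: pd.DataFrame, model: str = "variable_slope") -> pd.DataFrame:
    """Fit every compound in a tidy dose-response table; one row per compound."""
    rows = []
    for cid in df["compound_id"].unique():
        series = DoseResponseSeries.from_frame(df, cid)
        rows.append(fit_log_inhibitor(series, model=model).to_dict())
    return pd.DataFrame(rows)
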