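"""Synthetic 384-well screening data with known ground truth.

Generates event-level scatter/fluorescence mixtures (lymphocytes, debris,
doublets; CD4 and FoxP3 stains), injects compound effects (FoxP3 modulation,
toxicity-driven scatter shifts, additive autofluorescence) and assembles
continuous acquisition streams with per-well sip windows separated by shakes
and rinse blocks, so every downstream stage can be tested against truth
labels.

None of the distribution defaults are measurements; they are plausible
config values chosen to produce well-separated populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, four_pl
from .flow import ROLES, EventTable, PlateLayout, WellEntry, well_sort_key

__all__ = [
    "PopulationModel",
    "StainModel",
    "CompoundEffect",
    "AcquisitionProfile",
    "DEFAULT_CHANNELS",
    "default_populations",
    "default_stains",
    "design_layout",
    "simulate_well_events",
    "simulate_plate",
    "simulate_acquisition_stream",
    "simulate_dose_response",
]

CH_FSC_A = "FSC-A"
CH_FSC_H = "FSC-H"
CH_SSC_A = "SSC-A"
CH_CD4 = "PE-Cy7-A"
CH_FOXP3 = "V450-A"

DEFAULT_CHANNELS = [CH_FSC_A, CH_FSC_H, CH_SSC_A, CH_CD4, CH_FOXP3]


@dataclass
class PopulationModel:
    """One scatter population (lymphocyte, debris or doublet)."""

    name: str
    scatter_location: np.ndarray  # (FSC-A, SSC-A)
    scatter_spread: np.ndarray  # 2x2 covariance
    fsch_over_fsca: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.scatter_location = np.asarray(self.scatter_location, dtype=float)
        self.scatter_spread = np.asarray(self.scatter_spread, dtype=float)
        if self.scatter_location.shape != (2,):
            raise ValueError("scatter_location must be a 2-vector")
        if self.scatter_spread.shape != (2, 2):
            raise ValueError("scatter_spread must be 2x2")
        if not np.allclose(self.scatter_spread, self.scatter_spread.T):
            raise ValueError("scatter_spread must be symmetric")
        if np.any(np.linalg.eigvalsh(self.scatter_spread) <= 0):
            raise ValueError("scatter_spread must be positive-definite")
        if self.fsch_over_fsca <= 0:
            raise ValueError("fsch_over_fsca must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")


@dataclass
class StainModel:
    """Log-scale stained/unstained signal model for one fluorescence channel."""

    channel: str
    negative_location: float
    negative_spread: float
    positive_location: float
    positive_spread: float
    positive_fraction: float

    def __post_init__(self) -> None:
        if self.positive_location < self.negative_location:
            raise ValueError("positive_location must be >= negative_location")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.negative_spread <= 0 or self.positive_spread <= 0:
            raise ValueError("spreads must be positive")


@dataclass
class CompoundEffect:
    """Injected ground-truth effect of one compound well."""

    compound_id: str
    foxp3_multiplier: float = 1.0
    dead_fraction: float = 0.0
    autofluor_additive: dict[str, float] = field(default_factory=dict)
    viability_truth: bool = False

    def __post_init__(self) -> None:
        if self.foxp3_multiplier < 0:
            raise ValueError("foxp3_multiplier must be >= 0")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if any(v < 0 for v in self.autofluor_additive.values()):
            raise ValueError("autofluor_additive must be >= 0 per channel")


NEUTRAL_EFFECT = CompoundEffect(compound_id="DMSO")


@dataclass
class AcquisitionProfile:
    """Timing structure of a continuous per-well sipping acquisition."""

    sip_seconds: float = 13.5
    up_time_seconds: float = 1.0
    shake_every: int = 6
    shake_seconds: float = 4.0
    rinse_every: int = 12
    rinse_cycles: int = 3
    rinse_seconds: float = 1.0
    initial_shake_seconds: float = 30.0
    event_rate: float = 40.0
    inter_well_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sip_seconds", "up_time_seconds", "shake_seconds",
            "rinse_seconds", "initial_shake_seconds",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shake_every < 1 or self.rinse_every < 1 or self.rinse_cycles < 1:
            raise ValueError("shake/rinse cadence must be >= 1")
        if self.inter_well_rate < 0 or self.inter_well_rate >= self.event_rate:
            raise ValueError("inter_well_rate must be in [0, event_rate)")

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProfile":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def default_populations() -> list[PopulationModel]:
    return [
        PopulationModel(
            name="lymphocyte",
            scatter_location=(50_000.0, 20_000.0),
            scatter_spread=np.array([[8000.0**2, 0.25 * 8000 * 6000], [0.25 * 8000 * 6000, 6000.0**2]]),
            fsch_over_fsca=1.0,
            weight=0.75,
        ),
        PopulationModel(
            name="debris",
            scatter_location=(9_000.0, 4_000.0),
            scatter_spread=np.diag([2500.0**2, 1500.0**2]),
            fsch_over_fsca=1.0,
            weight=0.15,
        ),
        PopulationModel(
            name="doublet",
            scatter_location=(100_000.0, 24_000.0),
            scatter_spread=np.diag([12000.0**2, 7000.0**2]),
            fsch_over_fsca=0.5,
            weight=0.10,
        ),
    ]


def default_stains() -> list[StainModel]:
    return [
        StainModel(
            channel=CH_CD4,
            negative_location=float(np.log(150.0)),
            negative_spread=0.5,
            positive_location=float(np.log(15_000.0)),
            positive_spread=0.4,
            positive_fraction=0.65,
        ),
        StainModel(
            channel=CH_FOXP3,
            negative_location=float(np.log(300.0)),
            negative_spread=0.5,
            positive_location=float(np.log(5_000.0)),
            positive_spread=0.4,
            positive_fraction=0.10,
        ),
    ]


def design_layout(
    plate_id: str = "P1",
    n_compounds: int = 300,
    *,
    control_column: int = 24,
    n_dmso: int = 8,
    n_cd4_only: int = 4,
    n_unstained: int = 4,
    compound_prefix: str = "CMPD",
    concentration_um: float = 10.0,
) -> PlateLayout:
    """One-column control design: DMSO positives, CD4-only negatives and
    unstained controls share a column; compounds fill the rest row-major."""
    if n_dmso + n_cd4_only + n_unstained > 16:
        raise ValueError("control column holds at most 16 wells")
    wells: dict[str, WellEntry] = {}
    rows = [chr(ord("A") + i) for i in range(16)]
    roles = (
        ["dmso_positive"] * n_dmso
        + ["cd4_only_negative"] * n_cd4_only
        + ["unstained"] * n_unstained
    )
    for row, role in zip(rows, roles):
        wells[f"{row}{control_column:02d}"] = WellEntry(role=role, compound_id="DMSO" if role == "dmso_positive" else "")
    placed = 0
    for row in rows:
        for col in range(1, 25):
            if col == control_column or placed >= n_compounds:
                continue
            wells[f"{row}{col:02d}"] = WellEntry(
                role="compound",
                compound_id=f"{compound_prefix}{placed + 1:04d}",
                concentration_um=concentration_um,
            )
            placed += 1
    if placed < n_compounds:
        raise ValueError(f"plate can hold only {placed} compound wells")
    return PlateLayout(plate_id=plate_id, wells=wells)


# ---------------------------------------------------------------------------
# Event-level simulation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_well_events(
    role: str,
    effect: CompoundEffect | None,
    populations: list[PopulationModel] | None,
    stains: list[StainModel] | None,
    n_events: int,
    seed,
    *,
    channels: list[str] | None = None,
    dead_fsc_scale: float = 0.55,
    dead_extra_spread: float = 0.15,
    fsch_noise_sd: float = 0.05,
) -> EventTable:
    """Simulate one well; ground-truth labels ride along in ``labels``.

    Control roles always receive the neutral effect.  Unstained wells draw
    every fluorescence channel from its negative distribution; CD4-only wells
    draw the FoxP3 channel from its negative distribution.
    """
    if role not in ROLES:
        raise ValueError(f"unknown well role {role!r}; expected one of {sorted(ROLES)}")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    populations = populations if populations is not None else default_populations()
    stains = stains if stains is not None else default_stains()
    channels = channels if channels is not None else list(DEFAULT_CHANNELS)
    weights = np.array([p.weight for p in populations], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("population weights must sum to 1")

    if role == "compound":
        if effect is None:
            raise ValueError("compound wells require a CompoundEffect")
    else:
        effect = NEUTRAL_EFFECT

    rng = _as_rng(seed)
    pop_idx = rng.choice(len(populations), size=n_events, p=weights)

    events = np.zeros((n_events, len(channels)), dtype=float)
    i_fsca = channels.index(CH_FSC_A)
    i_fsch = channels.index(CH_FSC_H)
    i_ssca = channels.index(CH_SSC_A)

    fsca = np.empty(n_events)
    ssca = np.empty(n_events)
    ratio = np.empty(n_events)
    for k, pop in enumerate(populations):
        mask = pop_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        xy = rng.multivariate_normal(pop.scatter_location, pop.scatter_spread, size=m)
        fsca[mask] = xy[:, 0]
        ssca[mask] = xy[:, 1]
        ratio[mask] = pop.fsch_over_fsca

    # toxicity: a fraction of events becomes a shrunken, noisier scatter population
    dead = rng.random(n_events) < effect.dead_fraction
    if dead.any():
        jitter = np.exp(rng.normal(0.0, dead_extra_spread, size=int(dead.sum())))
        fsca[dead] *= dead_fsc_scale * jitter

    fsca = np.clip(fsca, 1.0, None)
    ssca = np.clip(ssca, 1.0, None)
    fsch = fsca * ratio * np.exp(rng.normal(0.0, fsch_noise_sd, size=n_events))

    events[:, i_fsca] = fsca
    events[:, i_fsch] = fsch
    events[:, i_ssca] = ssca

    pop_names = np.array([populations[k].name for k in pop_idx])
    stainable = pop_names != "debris"

    by_channel = {s.channel: s for s in stains}
    cd4_stain = by_channel.get(CH_CD4)
    foxp3_stain = by_channel.get(CH_FOXP3)

    cd4_label = np.zeros(n_events, dtype=bool)
    if cd4_stain is not None and role != "unstained":
        cd4_label = stainable & (rng.random(n_events) < cd4_stain.positive_fraction)

    foxp3_label = np.zeros(n_events, dtype=bool)
    if foxp3_stain is not None and role in ("compound", "dmso_positive"):
        p = float(np.clip(foxp3_stain.positive_fraction * effect.foxp3_multiplier, 0.0, 1.0))
        foxp3_label = cd4_label & (rng.random(n_events) < p)

    for stain in stains:
        idx = channels.index(stain.channel)
        if stain.channel == CH_CD4:
            positive = cd4_label
        elif stain.channel == CH_FOXP3:
            positive = foxp3_label
        else:
            positive = stainable & (rng.random(n_events) < stain.positive_fraction)
        loc = np.where(positive, stain.positive_location, stain.negative_location)
        spread = np.where(positive, stain.positive_spread, stain.negative_spread)
        events[:, idx] = np.exp(rng.normal(loc, spread))

    # additive autofluorescence on the linear scale, whole population
    for chan, amount in effect.autofluor_additive.items():
        events[:, channels.index(chan)] += amount

    labels = pd.DataFrame(
        {
            "population": pop_names,
            "cd4": cd4_label,
            "foxp3": foxp3_label,
            "live": ~dead,
        }
    )
    return EventTable(
        channels=channels, events=events, source=f"sim:{role}", labels=labels
    )


def simulate_plate(
    layout: PlateLayout,
    effects: dict[str, CompoundEffect] | None = None,
    *,
    populations: list[PopulationModel] | None = None,
    stains: list[StainModel] | None = None,
    n_events: int = 1000,
    seed: int = 0,
    channels: list[str] | None = None,
    **well_kwargs,
) -> tuple[dict[str, EventTable], pd.DataFrame]:
    """Simulate every well of a plate; returns (well tables, truth table).

    ``effects`` maps compound_id -> :class:`CompoundEffect`; every compound
    well must have an entry.
    """
    effects = effects or {}
    order = layout.acquisition_order()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(order))
    channels = channels if channels is not None else list(DEFAULT_CHANNELS)

    tables: dict[str, EventTable] = {}
    truth_rows = []
    stain_channels = [s.channel for s in (stains if stains is not None else default_stains())]
    for well, child in zip(order, children):
        entry = layout.wells[well]
        effect = None
        if entry.role == "compound":
            if entry.compound_id not in effects:
                raise ValueError(f"no CompoundEffect for compound well {well} ({entry.compound_id!r})")
            effect = effects[entry.compound_id]
        table = simulate_well_events(
            entry.role,
            effect,
            populations,
            stains,
            n_events,
            np.random.default_rng(child),
            channels=channels,
            **well_kwargs,
        )
        table.source = f"sim:{layout.plate_id}:{well}"
        tables[well] = table
        eff = effect if effect is not None else NEUTRAL_EFFECT
        row = {
            "plate_id": layout.plate_id,
            "well": well,
            "role": entry.role,
            "compound_id": entry.compound_id,
            "concentration_um": entry.concentration_um,
            "foxp3_multiplier": eff.foxp3_multiplier if entry.role in ("compound", "dmso_positive") else float("nan"),
            "dead_fraction": eff.dead_fraction,
            "viability_truth": eff.viability_truth,
        }
        for chan in stain_channels:
            row[f"autofluor_{chan}"] = eff.autofluor_additive.get(chan, 0.0)
        truth_rows.append(row)
    return tables, pd.DataFrame(truth_rows)


def simulate_acquisition_stream(
    plate_events: dict[str, EventTable],
    profile: AcquisitionProfile,
    seed: int = 0,
    *,
    order: list[str] | None = None,
) -> tuple[EventTable, pd.DataFrame]:
    """Concatenate per-well tables into one timed stream.

    Wells are sipped in acquisition order; shakes and rinse blocks insert the
    configured pauses, and background events arrive at ``inter_well_rate``
    outside the sip windows.  Returns the stream plus a truth table of sip
    windows; stream labels carry a ``truth_well`` column ('' = background).
    """
    if not plate_events:
        raise ValueError("no wells to stream")
    order = order if order is not None else sorted(plate_events, key=well_sort_key)
    missing = [w for w in order if w not in plate_events]
    if missing:
        raise ValueError(f"acquisition order references missing wells: {missing[:3]}")
    rng = _as_rng(seed)
    channels = plate_events[order[0]].channels

    t = profile.initial_shake_seconds
    windows = []
    gaps = [(0.0, t)]
    for i, well in enumerate(order):
        if i > 0:
            pause = profile.up_time_seconds
            if i % profile.shake_every == 0:
                pause += profile.shake_seconds
            if i % profile.rinse_every == 0:
                pause += profile.rinse_cycles * profile.rinse_seconds
            gaps.append((t, t + pause))
            t += pause
        windows.append((well, t, t + profile.sip_seconds))
        t += profile.sip_seconds

    chunks = []
    times = []
    label_frames = []
    for well, start, end in windows:
        table = plate_events[well]
        if table.channels != channels:
            raise ValueError(f"well {well} channel list differs from stream channels")
        ts = np.sort(rng.uniform(start, end, size=table.n_events))
        chunks.append(table.events)
        times.append(ts)
        lab = table.labels.copy() if table.labels is not None else pd.DataFrame(index=range(table.n_events))
        lab["truth_well"] = well
        label_frames.append(lab)

    n_background = 0
    if profile.inter_well_rate > 0:
        for start, end in gaps:
            k = rng.poisson(profile.inter_well_rate * (end - start))
            if k == 0:
                continue
            ts = np.sort(rng.uniform(start, end, size=k))
            vals = np.exp(rng.normal(np.log(50.0), 1.0, size=(k, len(channels))))
            chunks.append(vals)
            times.append(ts)
            lab = pd.DataFrame(index=range(k))
            lab["population"] = "background"
            lab["truth_well"] = ""
            label_frames.append(lab)
            n_background += k

    events = np.vstack(chunks)
    time = np.concatenate(times)
    labels = pd.concat(label_frames, ignore_index=True)
    sort = np.argsort(time, kind="stable")
    stream = EventTable(
        channels=list(channels),
        events=events[sort],
        time=time[sort],
        source="sim:stream",
        labels=labels.iloc[sort].reset_index(drop=True),
    )
    truth = pd.DataFrame(
        [
            {"well": w, "t_start": s, "t_end": e, "n_events": plate_events[w].n_events}
            for w, s, e in windows
        ]
    )
    truth.attrs["n_background"] = int(n_background)
    return stream, truth


def simulate_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    doses,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    compound_id: str = "CMPD",
) -> DoseResponseSeries:
    """Four-parameter-logistic responses plus Gaussian noise at each dose."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _as_rng(seed)
    all_doses = np.repeat(doses, replicates)
    rep_ids = np.tile(np.arange(replicates), len(doses))
    clean = four_pl(all_doses, ic50, hill, top, bottom)
    noisy = clean + (rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0)
    return DoseResponseSeries(
        compound_id=compound_id, doses=all_doses, responses=noisy, replicates=rep_ids
    )
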