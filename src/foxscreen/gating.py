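"""Hierarchical gating: lymphocytes -> singlets -> CD4+ -> FoxP3+/-.

Gate kinds: 2-D polygons on scatter (boundary counts as inside), FSC-H/FSC-A
ratio bands for singlet discrimination, fixed 1-D thresholds, and a KDE-based
automatic threshold on asinh-transformed fluorescence.  MFI throughout is the
median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .flow import EventTable, PlateLayout

__all__ = [
    "GateDefinition",
    "GateNode",
    "GateTree",
    "PopulationStats",
    "WellSummary",
    "polygon_gate",
    "ratio_band_gate",
    "threshold_gate",
    "evaluate_gate",
    "gate_lymphocytes",
    "gate_singlets",
    "auto_threshold",
    "run_gating_tree",
    "default_gate_tree",
    "default_lymphocyte_polygon",
    "fit_plate_cuts",
    "summarize_plate",
    "ASINH_COFACTOR",
]

ASINH_COFACTOR = 150.0
MIN_EVENTS_FLOOR = 100


@dataclass
class GateDefinition:
    name: str
    kind: str  # polygon2d | ratio_band | threshold1d
    channels: tuple[str, ...]
    params: dict = field(default_factory=dict)


def polygon_gate(name: str, ch_x: str, ch_y: str, vertices) -> GateDefinition:
    vertices = [(float(x), float(y)) for x, y in vertices]
    if len(vertices) < 3:
        raise ValueError("polygon gate needs at least 3 vertices")
    poly = shapely.Polygon(vertices)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"degenerate polygon for gate {name!r}")
    return GateDefinition(name, "polygon2d", (ch_x, ch_y), {"vertices": vertices})


def ratio_band_gate(name: str, ch_num: str, ch_den: str, low: float, high: float) -> GateDefinition:
    if not low < high:
        raise ValueError("ratio band requires low < high")
    return GateDefinition(name, "ratio_band", (ch_num, ch_den), {"low": float(low), "high": float(high)})


def threshold_gate(name: str, channel: str, cut: float, side: str = "above") -> GateDefinition:
    if not np.isfinite(cut):
        raise ValueError("threshold must be finite")
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    return GateDefinition(name, "threshold1d", (channel,), {"cut": float(cut), "side": side})


def evaluate_gate(table: EventTable, gate: GateDefinition) -> np.ndarray:
    """Boolean event mask for a single gate, ignoring any hierarchy."""
    if gate.kind == "polygon2d":
        x = table[gate.channels[0]]
        y = table[gate.channels[1]]
        poly = shapely.Polygon(gate.params["vertices"])
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"degenerate polygon for gate {gate.name!r}")
        pts = shapely.points(x, y)
        return shapely.covers(poly, pts)  # covers: boundary is inside
    if gate.kind == "ratio_band":
        num = table[gate.channels[0]]
        den = table[gate.channels[1]]
        ok = den > 0
        ratio = np.full(num.shape, np.nan)
        np.divide(num, den, out=ratio, where=ok)
        return ok & (ratio >= gate.params["low"]) & (ratio <= gate.params["high"])
    if gate.kind == "threshold1d":
        v = table[gate.channels[0]]
        cut = gate.params["cut"]
        return v > cut if gate.params["side"] == "above" else v <= cut
    raise ValueError(f"unknown gate kind {gate.kind!r}")


def gate_lymphocytes(table: EventTable, gate: GateDefinition) -> np.ndarray:
    if gate.kind != "polygon2d":
        raise ValueError("lymphocyte gate must be a 2-D polygon")
    return evaluate_gate(table, gate)


def gate_singlets(
    table: EventTable,
    low: float = 0.75,
    high: float = 1.25,
    *,
    fsc_h: str = "FSC-H",
    fsc_a: str = "FSC-A",
) -> np.ndarray:
    """Keep events whose FSC-H/FSC-A ratio lies within [low, high]; events
    with FSC-A <= 0 are excluded."""
    return evaluate_gate(table, ratio_band_gate("singlets", fsc_h, fsc_a, low, high))


def default_lymphocyte_polygon(
    ch_x: str = "FSC-A", ch_y: str = "SSC-A"
) -> GateDefinition:
    """Broad scatter gate excluding debris but keeping doublets (removed by
    the singlet band downstream).  Coordinates are config, not measurements."""
    return polygon_gate(
        "lymphocytes",
        ch_x,
        ch_y,
        [(22_000, -10_000), (135_000, -10_000), (135_000, 65_000), (22_000, 65_000)],
    )


# ---------------------------------------------------------------------------
# Automatic 1-D threshold
# ---------------------------------------------------------------------------


def auto_threshold(
    values: np.ndarray,
    *,
    cofactor: float = ASINH_COFACTOR,
    min_events: int = 50,
    grid_size: int = 512,
    min_mode_height: float = 0.05,
    fallback_quantile: float = 0.995,
    negative_control: np.ndarray | None = None,
) -> float:
    """Valley-seeking threshold between the two largest KDE modes.

    Values are asinh-transformed (handles negative compensated data) before a
    Gaussian KDE; the cut is the density minimum between the two tallest
    modes, mapped back to raw units.  If the estimate is unimodal the
    ``fallback_quantile`` of the (asinh) negative-control values is used
    instead; without a control that is an error, as is a constant input.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_events:
        raise ValueError(f"need at least {min_events} events, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("constant values: no spread to threshold")
    from scipy.stats import gaussian_kde

    t = np.arcsinh(values / cofactor)
    kde = gaussian_kde(t)
    grid = np.linspace(t.min(), t.max(), grid_size)
    dens = kde(grid)

    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    ) + 1
    peaks = [i for i in interior if dens[i] >= min_mode_height * dens.max()]
    # grid endpoints can host a mode too
    if dens[0] > dens[1] and dens[0] >= min_mode_height * dens.max():
        peaks.insert(0, 0)
    if dens[-1] > dens[-2] and dens[-1] >= min_mode_height * dens.max():
        peaks.append(grid_size - 1)

    if len(peaks) >= 2:
        top_two = sorted(sorted(peaks, key=lambda i: dens[i], reverse=True)[:2])
        lo, hi = top_two
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        return float(np.sinh(grid[valley]) * cofactor)

    if negative_control is None:
        raise ValueError("unimodal distribution and no negative control for fallback")
    nc = np.asarray(negative_control, dtype=float)
    nc = nc[np.isfinite(nc)]
    if nc.size < min_events:
        raise ValueError("negative control has too few events for the quantile fallback")
    cut_t = float(np.quantile(np.arcsinh(nc / cofactor), fallback_quantile))
    return float(np.sinh(cut_t) * cofactor)


# ---------------------------------------------------------------------------
# Gate tree
# ---------------------------------------------------------------------------


@dataclass
class GateNode:
    name: str
    gate: GateDefinition | None  # None only for the root
    parent: str | None


@dataclass
class GateTree:
    """Ordered parent->child gate list rooted at all events."""

    nodes: list[GateNode]

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError("gate tree must have exactly one root")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in gate tree")
        seen = set()
        for node in self.nodes:
            if node.parent is not None and node.parent not in seen:
                raise ValueError(f"node {node.name!r} listed before its parent {node.parent!r}")
            seen.add(node.name)

    @property
    def root(self) -> GateNode:
        return next(n for n in self.nodes if n.parent is None)

    def node(self, name: str) -> GateNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        import yaml

        doc = [
            {
                "name": n.name,
                "parent": n.parent,
                "gate": None
                if n.gate is None
                else {"kind": n.gate.kind, "channels": list(n.gate.channels), "params": n.gate.params},
            }
            for n in self.nodes
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateTree":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        nodes = []
        for item in doc:
            gate = None
            if item["gate"] is not None:
                g = item["gate"]
                gate = GateDefinition(item["name"], g["kind"], tuple(g["channels"]), g["params"])
            nodes.append(GateNode(name=item["name"], gate=gate, parent=item["parent"]))
        return cls(nodes)


@dataclass
class PopulationStats:
    name: str
    count: int
    fraction_of_parent: float
    fraction_of_total: float
    medians: dict[str, float]
    insufficient: bool = False


def run_gating_tree(
    table: EventTable, tree: GateTree, *, min_events: int = MIN_EVENTS_FLOOR
) -> dict[str, PopulationStats]:
    """Evaluate the tree top-down; every child population is the intersection
    of its gate with its parent mask.  Populations whose parent falls below
    ``min_events`` are flagged insufficient (stats still reported)."""
    masks: dict[str, np.ndarray] = {}
    stats: dict[str, PopulationStats] = {}
    total = table.n_events
    for node in tree.nodes:
        if node.parent is None:
            mask = np.ones(total, dtype=bool)
        else:
            mask = masks[node.parent] & evaluate_gate(table, node.gate)
        masks[node.name] = mask
        count = int(mask.sum())
        parent_count = total if node.parent is None else int(masks[node.parent].sum())
        medians = {
            ch: float(np.median(table[ch][mask])) if count else float("nan")
            for ch in table.channels
        }
        stats[node.name] = PopulationStats(
            name=node.name,
            count=count,
            fraction_of_parent=count / parent_count if parent_count else float("nan"),
            fraction_of_total=count / total if total else float("nan"),
            medians=medians,
            insufficient=parent_count < min_events,
        )
    return stats


def default_gate_tree(
    cd4_cut: float,
    foxp3_cut: float,
    *,
    lymph_gate: GateDefinition | None = None,
    singlet_band: tuple[float, float] = (0.75, 1.25),
    ch_fsc_a: str = "FSC-A",
    ch_fsc_h: str = "FSC-H",
    ch_cd4: str = "PE-Cy7-A",
    ch_foxp3: str = "V450-A",
) -> GateTree:
    """The five-node tree: all -> lymphocytes -> singlets -> CD4+ -> FoxP3+/-.

    FoxP3+ (above cut) and FoxP3- (at or below cut) partition CD4+ exactly.
    """
    lymph = lymph_gate if lymph_gate is not None else default_lymphocyte_polygon(ch_fsc_a)
    return GateTree(
        [
            GateNode("all_events", None, None),
            GateNode("lymphocytes", lymph, "all_events"),
            GateNode(
                "singlets",
                ratio_band_gate("singlets", ch_fsc_h, ch_fsc_a, *singlet_band),
                "lymphocytes",
            ),
            GateNode("cd4_pos", threshold_gate("cd4_pos", ch_cd4, cd4_cut, "above"), "singlets"),
            GateNode("foxp3_pos", threshold_gate("foxp3_pos", ch_foxp3, foxp3_cut, "above"), "cd4_pos"),
            GateNode("foxp3_neg", threshold_gate("foxp3_neg", ch_foxp3, foxp3_cut, "below"), "cd4_pos"),
        ]
    )


# ---------------------------------------------------------------------------
# Plate-level summaries
# ---------------------------------------------------------------------------


@dataclass
class WellSummary:
    well: str
    plate_id: str
    role: str
    compound_id: str
    concentration_um: float
    foxp3_pct_cd4: float
    cd4_pct_singlets: float
    fsch_mfi: float
    v450_mfi_pos: float
    v450_mfi_neg: float
    n_events: int
    n_lymphocytes: int
    n_singlets: int
    n_cd4: int
    n_foxp3_pos: int
    n_foxp3_neg: int
    live_pct: float = float("nan")


def fit_plate_cuts(
    tables: dict[str, EventTable],
    layout: PlateLayout,
    *,
    lymph_gate: GateDefinition | None = None,
    singlet_band: tuple[float, float] = (0.75, 1.25),
    ch_fsc_a: str = "FSC-A",
    ch_fsc_h: str = "FSC-H",
    ch_cd4: str = "PE-Cy7-A",
    ch_foxp3: str = "V450-A",
    **auto_kwargs,
) -> tuple[float, float]:
    """Plate-global CD4 and FoxP3 cuts fitted on pooled DMSO-positive wells,
    with unstained wells (when present) as the quantile fallback control."""
    lymph = lymph_gate if lymph_gate is not None else default_lymphocyte_polygon(ch_fsc_a)
    dmso_wells = layout.wells_with_role("dmso_positive")
    if not dmso_wells:
        raise ValueError("no dmso_positive wells to fit plate-global gates")

    def pooled(wells: list[str], channel: str, within_cd4: float | None = None) -> np.ndarray:
        cols = []
        for w in wells:
            if w not in tables:
                continue
            t = tables[w]
            mask = gate_lymphocytes(t, lymph) & gate_singlets(
                t, *singlet_band, fsc_h=ch_fsc_h, fsc_a=ch_fsc_a
            )
            if within_cd4 is not None:
                mask &= t[ch_cd4] > within_cd4
            cols.append(t[channel][mask])
        return np.concatenate(cols) if cols else np.array([])

    unstained = layout.wells_with_role("unstained")
    cd4_nc = pooled(unstained, ch_cd4) if unstained else None
    cd4_cut = auto_threshold(pooled(dmso_wells, ch_cd4), negative_control=cd4_nc, **auto_kwargs)
    foxp3_nc = pooled(unstained, ch_foxp3) if unstained else None
    foxp3_cut = auto_threshold(
        pooled(dmso_wells, ch_foxp3, within_cd4=cd4_cut),
        negative_control=foxp3_nc,
        **auto_kwargs,
    )
    return float(cd4_cut), float(foxp3_cut)


def summarize_plate(
    tables: dict[str, EventTable],
    layout: PlateLayout,
    *,
    cd4_cut: float | None = None,
    foxp3_cut: float | None = None,
    lymph_gate: GateDefinition | None = None,
    singlet_band: tuple[float, float] = (0.75, 1.25),
    min_events: int = MIN_EVENTS_FLOOR,
    ch_fsc_a: str = "FSC-A",
    ch_fsc_h: str = "FSC-H",
    ch_cd4: str = "PE-Cy7-A",
    ch_foxp3: str = "V450-A",
) -> tuple[pd.DataFrame, dict]:
    """Gate every well of a plate and emit one summary row per well.

    Cuts default to plate-global values fitted on pooled DMSO wells.  Also
    returns plate-level statistics, including the FSC-H median of events
    pooled across all DMSO wells (the toxicity-ratio denominator).
    """
    if cd4_cut is None or foxp3_cut is None:
        fitted = fit_plate_cuts(
            tables, layout, lymph_gate=lymph_gate, singlet_band=singlet_band,
            ch_fsc_a=ch_fsc_a, ch_fsc_h=ch_fsc_h, ch_cd4=ch_cd4, ch_foxp3=ch_foxp3,
        )
        cd4_cut = cd4_cut if cd4_cut is not None else fitted[0]
        foxp3_cut = foxp3_cut if foxp3_cut is not None else fitted[1]
    tree = default_gate_tree(
        cd4_cut, foxp3_cut, lymph_gate=lymph_gate, singlet_band=singlet_band,
        ch_fsc_a=ch_fsc_a, ch_fsc_h=ch_fsc_h, ch_cd4=ch_cd4, ch_foxp3=ch_foxp3,
    )

    rows = []
    dmso_fsch_pool = []
    for well in layout.acquisition_order():
        if well not in tables:
            continue
        table = tables[well]
        entry = layout.wells[well]
        stats = run_gating_tree(table, tree, min_events=min_events)
        n_cd4 = stats["cd4_pos"].count
        n_pos = stats["foxp3_pos"].count
        n_neg = stats["foxp3_neg"].count
        live_pct = float("nan")
        if table.labels is not None and "live" in table.labels:
            live_pct = 100.0 * float(table.labels["live"].mean())
        rows.append(
            WellSummary(
                well=well,
                plate_id=layout.plate_id,
                role=entry.role,
                compound_id=entry.compound_id,
                concentration_um=entry.concentration_um,
                foxp3_pct_cd4=100.0 * n_pos / n_cd4 if n_cd4 else float("nan"),
                cd4_pct_singlets=100.0 * n_cd4 / stats["singlets"].count
                if stats["singlets"].count
                else float("nan"),
                fsch_mfi=stats["lymphocytes"].medians[ch_fsc_h],
                v450_mfi_pos=stats["foxp3_pos"].medians[ch_foxp3],
                v450_mfi_neg=stats["foxp3_neg"].medians[ch_foxp3],
                n_events=table.n_events,
                n_lymphocytes=stats["lymphocytes"].count,
                n_singlets=stats["singlets"].count,
                n_cd4=n_cd4,
                n_foxp3_pos=n_pos,
                n_foxp3_neg=n_neg,
                live_pct=live_pct,
            ).__dict__
        )
        if entry.role == "dmso_positive":
            lymph_mask = gate_lymphocytes(table, lymph_gate or default_lymphocyte_polygon(ch_fsc_a))
            dmso_fsch_pool.append(table[ch_fsc_h][lymph_mask])

    plate_stats = {
        "plate_id": layout.plate_id,
        "cd4_cut": float(cd4_cut),
        "foxp3_cut": float(foxp3_cut),
        "dmso_pooled_fsch_mfi": float(np.median(np.concatenate(dmso_fsch_pool)))
        if dmso_fsch_pool
        else float("nan"),
    }
    return pd.DataFrame(rows), plate_stats
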