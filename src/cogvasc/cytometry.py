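"""Small-particle flow-cytometry analysis of plasma extracellular vesicles.

Events carry three logical fluorescence channels — a pooled endothelial
channel (CD31/CD144/CD105, one fluorophore), a pooled lymphocyte/platelet
exclusion channel (CD3/CD41), and a MAL channel marking CNS endothelium —
plus an estimated diameter.  Gating is sequential: exclude
lymphocyte/platelet-positive events, call the remainder endothelial by the
pooled channel, then split endothelial events by MAL into cerebrovascular
(CEEV, MAL+) and peripheral (EEV-only, MAL-).  Positivity thresholds come
from fluorescence-minus-one (FMO) controls, never from the stained sample.

The CEEV ratio is 100 x CEEV / (CEEV + EEV-only); concentrations are
events per μL of plasma after dilution correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvEventTable",
    "GateSet",
    "EvSummary",
    "CHANNELS",
    "SIZE_BINS_NM",
    "derive_gates",
    "gate_events",
    "ceev_ratio",
    "concentration",
    "size_distribution",
    "average_replicates",
    "summarize_aliquot",
]

#: Logical fluorescence channels (column names in event tables).
CHANNELS = ("endo_ch", "lymph_platelet_ch", "mal_ch")

#: Diameter bin edges (nm); bins are half-open [lo, hi).
SIZE_BINS_NM = (0.0, 180.0, 600.0, 1000.0, np.inf)

#: Population labels produced by gating, a partition of all events.
POPULATIONS = ("excluded_lymph_platelet", "ceev", "eev_only", "mal_other", "negative")


@dataclass
class EvEventTable:
    """Per-event fluorescence + diameter with acquisition metadata."""

    events: pd.DataFrame  # columns: endo_ch, lymph_platelet_ch, mal_ch, diameter_nm
    flowrate_ul_min: float = 1.5
    duration_s: float = 120.0
    dilution_factor: float = 200.0
    sample_id: str = ""
    ground_truth: pd.Series | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS + ("diameter_nm",) if c not in self.events]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        if (self.events["diameter_nm"] <= 0).any():
            raise ValueError("diameters must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def acquired_volume_ul(self) -> float:
        return self.flowrate_ul_min * self.duration_s / 60.0

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class GateSet:
    """Per-channel positivity thresholds derived from FMO controls."""

    thresholds: dict[str, float]
    percentile: float
    fmo_sample_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.thresholds.values()):
            raise ValueError("gate thresholds must be finite")


@dataclass
class EvSummary:
    """Counts, ratio, concentrations, and size bins for one aliquot."""

    counts: dict[str, int]
    ceev_ratio_pct: float | None
    ceev_conc_events_per_ul: float
    eev_conc_events_per_ul: float
    mal_other_conc_events_per_ul: float
    size_bin_counts: dict[str, int]
    sample_id: str = ""


def derive_gates(
    fmo_tables: dict[str, EvEventTable], percentile: float = 99.9
) -> GateSet:
    """Positivity threshold per channel = ``percentile`` of the FMO events.

    Each FMO table omits exactly the stain of the channel it gates, so its
    distribution in that channel is pure background.
    """
    thresholds: dict[str, float] = {}
    ids: dict[str, str] = {}
    for ch in CHANNELS:
        if ch not in fmo_tables:
            raise KeyError(f"missing FMO control for channel {ch!r}")
        tab = fmo_tables[ch]
        thresholds[ch] = float(np.percentile(tab.events[ch], percentile))
        ids[ch] = tab.sample_id
    return GateSet(thresholds=thresholds, percentile=percentile, fmo_sample_ids=ids)


def gate_events(table: EvEventTable, gates: GateSet) -> pd.Series:
    """Sequential gating; returns one population label per event.

    1. events positive in the lymphocyte/platelet channel are excluded;
    2. remaining events positive in the endothelial channel are split by
       MAL into ``ceev`` (MAL+) and ``eev_only`` (MAL-);
    3. endothelial-negative, MAL-positive events are ``mal_other``;
    4. everything else is ``negative``.
    """
    ev = table.events
    thr = gates.thresholds
    lp = ev["lymph_platelet_ch"] > thr["lymph_platelet_ch"]
    endo = ev["endo_ch"] > thr["endo_ch"]
    mal = ev["mal_ch"] > thr["mal_ch"]
    label = np.full(len(ev), "negative", dtype=object)
    label[~lp & endo & mal] = "ceev"
    label[~lp & endo & ~mal] = "eev_only"
    label[~lp & ~endo & mal] = "mal_other"
    label[lp] = "excluded_lymph_platelet"
    return pd.Series(label, index=ev.index, name="population")


def ceev_ratio(n_ceev: int, n_eev_only: int) -> float | None:
    """100 x CEEV / total endothelial.  None (flagged) if no endothelial
    events were observed."""
    total = n_ceev + n_eev_only
    if total == 0:
        warnings.warn("no endothelial events; CEEV ratio undefined")
        return None
    return 100.0 * n_ceev / total


def concentration(
    count: int,
    flowrate_ul_min: float = 1.5,
    duration_s: float = 120.0,
    dilution_factor: float = 1.0,
) -> float:
    """Plasma concentration in events/μL, corrected for dilution."""
    volume_ul = flowrate_ul_min * duration_s / 60.0
    if volume_ul <= 0:
        raise ValueError("acquired volume must be positive")
    return count / volume_ul * dilution_factor


def size_distribution(diameters_nm: np.ndarray, bins=SIZE_BINS_NM) -> dict[str, int]:
    """Counts in half-open diameter bins [lo, hi)."""
    d = np.asarray(diameters_nm, dtype=float)
    counts, _ = np.histogram(d, bins=np.asarray(bins))
    names = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        names.append(f"[{lo:g},{hi_s})")
    return dict(zip(names, (int(c) for c in counts)))


def summarize_aliquot(table: EvEventTable, gates: GateSet) -> EvSummary:
    """Gate one aliquot and compute ratio, concentrations, and size bins."""
    labels = gate_events(table, gates)
    counts = {pop: int((labels == pop).sum()) for pop in POPULATIONS}
    n_ceev, n_eev = counts["ceev"], counts["eev_only"]
    kw = dict(
        flowrate_ul_min=table.flowrate_ul_min,
        duration_s=table.duration_s,
        dilution_factor=table.dilution_factor,
    )
    ceev_d = table.events.loc[labels == "ceev", "diameter_nm"].to_numpy()
    return EvSummary(
        counts=counts,
        ceev_ratio_pct=ceev_ratio(n_ceev, n_eev),
        ceev_conc_events_per_ul=concentration(n_ceev, **kw),
        eev_conc_events_per_ul=concentration(n_ceev + n_eev, **kw),
        mal_other_conc_events_per_ul=concentration(counts["mal_other"], **kw),
        size_bin_counts=size_distribution(ceev_d),
        sample_id=table.sample_id,
    )


def average_replicates(summaries: list[EvSummary]) -> dict[str, float]:
    """Arithmetic mean of each summary quantity across aliquots."""
    if not summaries:
        raise ValueError("need at least one aliquot")
    if len(summaries) == 1:
        warnings.warn("single aliquot: replicate averaging is a passthrough")
    ratios = [s.ceev_ratio_pct for s in summaries if s.ceev_ratio_pct is not None]
    out = {
        "ceev_ratio_pct": float(np.mean(ratios)) if ratios else np.nan,
        "ceev_conc_events_per_ul": float(
            np.mean([s.ceev_conc_events_per_ul for s in summaries])
        ),
        "eev_conc_events_per_ul": float(
            np.mean([s.eev_conc_events_per_ul for s in summaries])
        ),
        "mal_other_conc_events_per_ul": float(
            np.mean([s.mal_other_conc_events_per_ul for s in summaries])
        ),
    }
    bins = summaries[0].size_bin_counts.keys()
    for b in bins:
        out[f"size_{b}"] = float(np.mean([s.size_bin_counts[b] for s in summaries]))
    return out
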