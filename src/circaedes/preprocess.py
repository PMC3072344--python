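"""Raw spot tables -> reconstructed 12-point M-value profiles.

Pipeline: drop spike-in control spots, subtract median background per
channel (with a positive floor so log-ratios stay defined), form
M = log2(sample / reference) against the common 24 h reference pool,
keep technical replicate spots as separate entities, and concatenate the
first six timecourse points of the two biological replicates into one
continuous 48 h series sampled every 4 h (timestamps relabeled 0..44 h,
nominally starting 9 am).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ArrayLayout, ExperimentDesign, SpotTable

__all__ = [
    "ExpressionProfile",
    "PreprocessLog",
    "remove_spikes",
    "background_correct",
    "relative_intensity",
    "spot_m_values",
    "collapse_replicate_spots",
    "reconstruct_timeline",
    "preprocess_experiment",
    "write_profile_matrix",
    "read_profile_matrix",
]

DEFAULT_FLOOR = 1.0  # intensity units; keeps log2 defined when fg <= bg


@dataclass
class ExpressionProfile:
    """One technical spot's reconstructed relative-intensity series."""

    probe_id: str
    replicate_index: int
    values: np.ndarray  # M-values, log2 scale
    timestamps: np.ndarray  # hours, constant step

    @property
    def profile_id(self) -> str:
        return f"{self.probe_id}.{self.replicate_index}"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps must have equal length")


@dataclass
class PreprocessLog:
    """Record counts at every filtering step (conservation check)."""

    rows_in: int = 0
    spikes_removed: int = 0
    floored_spots: int = 0
    incomplete_excluded: list[str] = field(default_factory=list)
    profiles_out: int = 0

    def as_lines(self) -> list[str]:
        lines = [
            f"rows_in\t{self.rows_in}",
            f"spikes_removed\t{self.spikes_removed}",
            f"floored_spots\t{self.floored_spots}",
            f"profiles_out\t{self.profiles_out}",
        ]
        lines += [f"incomplete_excluded\t{pid}" for pid in self.incomplete_excluded]
        return lines


def remove_spikes(table: SpotTable, layout: ArrayLayout) -> SpotTable:
    """Drop spike-in control spots, preserving original spot order."""
    if len(table.data) != layout.n_spots:
        raise ValueError(
            f"table has {len(table.data)} rows but layout has {layout.n_spots} spots"
        )
    mask = np.array([not s.is_spike for s in layout.spots])
    if not (table.data["probe_id"].to_numpy() == [s.probe_id for s in layout.spots]).all():
        raise ValueError("table rows do not match layout spot order")
    return SpotTable(
        table.timepoint_label, table.replicate_id, table.data.loc[mask].reset_index(drop=True)
    )


def background_correct(fg, bg, floor: float = DEFAULT_FLOOR):
    """max(fg - bg, floor): median-background subtraction with a positive floor."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.maximum(np.asarray(fg, dtype=float) - np.asarray(bg, dtype=float), floor)


def relative_intensity(sample_corrected, reference_corrected):
    """M = log2(sample/reference); positive M means above the 24 h reference."""
    s = np.asarray(sample_corrected, dtype=float)
    r = np.asarray(reference_corrected, dtype=float)
    if np.any(s <= 0) or np.any(r <= 0):
        raise ValueError("corrected intensities must be positive")
    return np.log2(s / r)


def spot_m_values(
    table: SpotTable, layout: ArrayLayout, floor: float = DEFAULT_FLOOR
) -> tuple[pd.DataFrame, int]:
    """Per-spot M-values for one array after spike removal and correction.

    Returns (frame with probe_id/replicate_index/m, number of floored spots).
    """
    clean = remove_spikes(table, layout)
    fg1 = clean.data["fg_median_ch1"].to_numpy()
    bg1 = clean.data["bg_median_ch1"].to_numpy()
    fg2 = clean.data["fg_median_ch2"].to_numpy()
    bg2 = clean.data["bg_median_ch2"].to_numpy()
    c1 = background_correct(fg1, bg1, floor)
    c2 = background_correct(fg2, bg2, floor)
    floored = int(np.sum(fg1 - bg1 < floor) + np.sum(fg2 - bg2 < floor))
    out = clean.data[["probe_id", "replicate_index"]].copy()
    out["m"] = relative_intensity(c1, c2)
    return out, floored


def collapse_replicate_spots(
    m_frames: dict[float, pd.DataFrame], average: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble per-spot M series across timepoints for one biological replicate.

    ``m_frames`` maps timepoint hour -> per-spot M frame.  Technical
    replicate spots are kept as separate entities (one series per spot);
    the optional ``average`` mode collapses them to one series per probe.
    Spots missing any timepoint are excluded and reported.

    Returns (wide frame indexed by "probe.spot" with timepoint columns,
    excluded spot ids).
    """
    hours = sorted(m_frames)
    pieces = []
    for h in hours:
        f = m_frames[h]
        s = f.set_index(
            f["probe_id"].astype(str) + "." + f["replicate_index"].astype(str)
        )["m"]
        s.name = h
        pieces.append(s)
    wide = pd.concat(pieces, axis=1)
    complete = wide.dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    if average:
        probe = complete.index.to_series().str.rsplit(".", n=1).str[0]
        complete = complete.groupby(probe.to_numpy()).mean()
        complete.index = pd.Index([f"{p}.avg" for p in complete.index])
    return complete, excluded


def reconstruct_timeline(
    rep1: np.ndarray, rep2: np.ndarray, sampling_interval: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the first six points of each replicate into a 48 h series.

    The two biological replicates are treated as independent timelines
    over the same circadian day; taking six 4 h steps from each yields a
    continuous two-cycle, 12-point series with timestamps 0..44 h.
    """
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if len(rep1) < 6 or len(rep2) < 6:
        raise ValueError("each replicate series needs at least 6 points")
    values = np.concatenate([rep1[:6], rep2[:6]])
    timestamps = np.arange(12) * sampling_interval
    return values, timestamps


def preprocess_experiment(
    tables: list[SpotTable],
    layout: ArrayLayout,
    design: ExperimentDesign | None = None,
    floor: float = DEFAULT_FLOOR,
    average_technical: bool = False,
) -> tuple[pd.DataFrame, PreprocessLog]:
    """Full preprocessing: spot tables -> profile matrix.

    Returns a DataFrame whose rows are technical-spot profiles
    ("probe.spot" ids), columns the 12 reconstructed timestamps (hours),
    plus a :class:`PreprocessLog` accounting for every dropped record.
    """
    if design is None:
        design = ExperimentDesign()
    log = PreprocessLog()
    by_rep: dict[int, dict[float, pd.DataFrame]] = {}
    for tab in tables:
        log.rows_in += len(tab.data)
        m, floored = spot_m_values(tab, layout, floor)
        log.spikes_removed += layout.n_spike
        log.floored_spots += floored
        by_rep.setdefault(tab.replicate_id, {})[tab.timepoint_label] = m
    if sorted(by_rep) != list(range(1, design.n_replicates + 1)):
        raise ValueError(
            f"expected replicates {list(range(1, design.n_replicates + 1))}, got {sorted(by_rep)}"
        )
    series = {}
    excluded_all: set[str] = set()
    for rep, frames in by_rep.items():
        wide, excl = collapse_replicate_spots(frames, average=average_technical)
        series[rep] = wide
        excluded_all.update(excl)
    # a spot must be complete in both replicates
    common = series[1].index.intersection(series[2].index)
    for rep in series:
        only = set(series[rep].index) - set(common)
        excluded_all.update(only)
    log.incomplete_excluded = sorted(excluded_all)

    rows = {}
    timestamps = None
    for pid in common:
        v, ts = reconstruct_timeline(
            series[1].loc[pid].to_numpy(),
            series[2].loc[pid].to_numpy(),
            design.sampling_interval,
        )
        rows[pid] = v
        timestamps = ts
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=timestamps)
    matrix.index.name = "profile_id"
    matrix = matrix.sort_index()
    log.profiles_out = len(matrix)
    return matrix, log


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="profile_id")
    m.columns = m.columns.astype(float)
    return m
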