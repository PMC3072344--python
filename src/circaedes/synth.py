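"""Synthetic two-color microarray data with planted circadian truth.

Emulates the study design this package analyses: a spotted oligo array
whose probes are replicated 2-4x plus spike-in control spots, hybridized
at 10 collection timepoints (a 24 h reference pool and a 72-104 h
timecourse sampled every 4 h) in two biological replicates.  Channel 1
carries the timepoint sample, channel 2 always carries the common 24 h
reference pool, so the log2 ratio of background-corrected intensities is
the probe's M-value relative to the reference.

Rhythmic probes oscillate on the log2-ratio scale:

    M(t) = baseline + amplitude * cos(2*pi*(t - 6*phase_class)/24)

with phase_class in {0,1,2,3} placing the peak at 0/6/12/18 h after the
start of the reconstructed series.  Technical noise is multiplicative
log-normal on the foreground intensities (i.i.d. per spot on the log
scale).  Every stochastic routine requires an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spot",
    "ArrayLayout",
    "ExperimentDesign",
    "SpotTable",
    "generate_layout",
    "make_truth_table",
    "simulate_experiment",
    "write_layout",
    "read_layout",
    "write_truth_table",
    "read_truth_table",
    "write_spot_tables",
    "read_spot_tables",
]

SPIKE_PREFIX = "spike_"
PROBE_PREFIX = "probe_"


@dataclass(frozen=True)
class Spot:
    """One physical feature on the array."""

    probe_id: str
    replicate_index: int
    is_spike: bool


@dataclass
class ArrayLayout:
    """Spot manifest defining one array's geometry.

    ``spots`` lists every feature in layout order.  Probe spots for a
    probe of multiplicity m carry replicate_index 1..m; spike-in spots
    live in a reserved ``spike_`` id namespace disjoint from probes.
    """

    spots: list[Spot]
    n_probes_by_multiplicity: dict[int, int]
    n_spike: int

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_nonspike(self) -> int:
        return self.n_spots - self.n_spike

    def probe_ids(self) -> list[str]:
        """Unique non-spike probe ids in layout order."""
        seen: dict[str, None] = {}
        for s in self.spots:
            if not s.is_spike and s.probe_id not in seen:
                seen[s.probe_id] = None
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [s.probe_id for s in self.spots],
                "replicate_index": [s.replicate_index for s in self.spots],
                "is_spike": [int(s.is_spike) for s in self.spots],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArrayLayout":
        spots = [
            Spot(str(r.probe_id), int(r.replicate_index), bool(r.is_spike))
            for r in df.itertuples(index=False)
        ]
        mult: dict[str, int] = {}
        for s in spots:
            if not s.is_spike:
                mult[s.probe_id] = max(mult.get(s.probe_id, 0), s.replicate_index)
        by_m: dict[int, int] = {}
        for m in mult.values():
            by_m[m] = by_m.get(m, 0) + 1
        return cls(spots, by_m, sum(1 for s in spots if s.is_spike))


def generate_layout(
    n_dup2: int, n_dup3: int, n_dup4: int, n_spike: int
) -> ArrayLayout:
    """Deterministically build a layout with the given probe multiplicities.

    The study array has 20,692 probes spotted twice, 793 thrice, 10 four
    times (43,803 probe spots) plus 1,417 spike-in control spots, for
    45,220 features in total.

    Parameters are the probe counts per multiplicity class and the number
    of spike-in spots; all must be nonnegative.
    """
    for name, v in (
        ("n_dup2", n_dup2),
        ("n_dup3", n_dup3),
        ("n_dup4", n_dup4),
        ("n_spike", n_spike),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    spots: list[Spot] = []
    probe_no = 0
    for mult, count in ((2, n_dup2), (3, n_dup3), (4, n_dup4)):
        for _ in range(count):
            probe_no += 1
            pid = f"{PROBE_PREFIX}{probe_no:06d}"
            for rep in range(1, mult + 1):
                spots.append(Spot(pid, rep, False))
    for i in range(1, n_spike + 1):
        spots.append(Spot(f"{SPIKE_PREFIX}{i:04d}", 1, True))
    by_m = {m: c for m, c in ((2, n_dup2), (3, n_dup3), (4, n_dup4)) if c}
    return ArrayLayout(spots, by_m, n_spike)


@dataclass
class ExperimentDesign:
    """Sampling design: reference pool hour, timecourse hours, replicates.

    Defaults mirror the study: heads collected at 24 h (reference pool)
    and at 72..104 h every 4 h, two biological replicate cages, with the
    first six timecourse points of each replicate concatenated downstream
    into a 12-point / 48 h reconstructed series.
    """

    reference_hour: float = 24.0
    sample_hours: tuple[float, ...] = tuple(float(h) for h in range(72, 105, 4))
    n_replicates: int = 2
    sampling_interval: float = 4.0

    @property
    def n_collection_timepoints(self) -> int:
        """Distinct head-collection timepoints (reference + timecourse)."""
        return 1 + len(self.sample_hours)


@dataclass
class SpotTable:
    """Raw spot-level intensities for one hybridized array.

    One row per layout spot, in layout order.  Channel 1 is the timepoint
    sample, channel 2 the common 24 h reference pool of the matching
    biological replicate.
    """

    timepoint_label: float
    replicate_id: int
    data: pd.DataFrame  # probe_id, replicate_index, fg/bg medians x2 channels

    @property
    def label(self) -> str:
        h = self.timepoint_label
        hs = f"{h:g}"
        return f"{hs}.{self.replicate_id}"


def make_truth_table(
    probe_ids: list[str],
    frac_rhythmic: float = 0.5,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    baseline: float = 0.0,
    seed: int | None = None,
    phase_classes: tuple[int, ...] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Plant ground truth: which probes oscillate, at what phase/amplitude.

    Returns a DataFrame indexed by probe_id with columns is_rhythmic,
    amplitude, phase_class (only meaningful when rhythmic), baseline and
    noise_sd (both log2-scale).  ``amplitude / noise_sd`` is the planted
    signal-to-noise ratio.  Phases are drawn uniformly from the four
    discrete classes the 12-point design can resolve.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must be in [0, 1]")
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    n_rhy = int(round(frac_rhythmic * n))
    is_rhy = np.zeros(n, dtype=bool)
    is_rhy[rng.choice(n, size=n_rhy, replace=False)] = True
    phases = np.full(n, -1, dtype=int)
    phases[is_rhy] = rng.choice(phase_classes, size=n_rhy)
    return pd.DataFrame(
        {
            "is_rhythmic": is_rhy,
            "amplitude": np.where(is_rhy, amplitude, 0.0),
            "phase_class": phases,
            "baseline": baseline,
            "noise_sd": noise_sd,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def _expected_log_ratio(truth_row: pd.Series, t_hours: float, period: float = 24.0) -> float:
    m = float(truth_row["baseline"])
    if bool(truth_row["is_rhythmic"]):
        shift = (period / 4.0) * float(truth_row["phase_class"])
        m += float(truth_row["amplitude"]) * math.cos(
            2.0 * math.pi * (t_hours - shift) / period
        )
    return m


def simulate_experiment(
    layout: ArrayLayout,
    truth: pd.DataFrame,
    design: ExperimentDesign | None = None,
    seed: int | None = None,
    abundance: float = 10.0,
    bg_level: float = 50.0,
    bg_noise_sd: float = 5.0,
    spike_level: float = 12.0,
    period: float = 24.0,
) -> list[SpotTable]:
    """Simulate one full hybridization series from layout + planted truth.

    The timecourse clock for the oscillation term starts at the first
    timecourse collection (72 h maps to t = 0 of the reconstructed
    series), so a phase-0 probe peaks at the series start.  Reference
    channel 2 carries the probe's abundance without oscillation or
    baseline offset; channel 1 carries abundance + baseline + the cosine
    term, both perturbed by i.i.d. log-normal spot noise, so the expected
    M-value is baseline + amplitude*cos(2*pi*(t - 6*phase)/24).

    Intensities are foreground = background + 2**(log2 level + noise);
    subtracting the recorded background therefore recovers the signal
    component exactly when ``noise_sd`` is zero.
    """
    if design is None:
        design = ExperimentDesign()
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    probe_ids = layout.probe_ids()
    missing = set(truth.index) - set(probe_ids)
    if missing:
        raise ValueError(
            f"truth table contains probes absent from layout: {sorted(missing)[:3]}..."
            if len(missing) > 3
            else f"truth table contains probes absent from layout: {sorted(missing)}"
        )
    absent = set(probe_ids) - set(truth.index)
    if absent:
        raise ValueError("layout probes missing from truth table")

    rng = np.random.default_rng(seed)
    spot_pids = np.array([s.probe_id for s in layout.spots])
    spot_reps = np.array([s.replicate_index for s in layout.spots])
    spot_is_spike = np.array([s.is_spike for s in layout.spots])
    n_spots = layout.n_spots

    # per-spot truth vectors (spikes get flat truth at spike_level)
    t_idx = truth.reindex(spot_pids[~spot_is_spike])
    base = np.zeros(n_spots)
    amp = np.zeros(n_spots)
    phase = np.zeros(n_spots)
    nsd = np.zeros(n_spots)
    level0 = np.full(n_spots, abundance)
    base[~spot_is_spike] = t_idx["baseline"].to_numpy()
    amp[~spot_is_spike] = np.where(
        t_idx["is_rhythmic"].to_numpy(), t_idx["amplitude"].to_numpy(), 0.0
    )
    phase[~spot_is_spike] = np.where(
        t_idx["is_rhythmic"].to_numpy(), t_idx["phase_class"].to_numpy(), 0.0
    )
    nsd[~spot_is_spike] = t_idx["noise_sd"].to_numpy()
    level0[spot_is_spike] = spike_level

    t0 = design.sample_hours[0]
    tables: list[SpotTable] = []
    for rep in range(1, design.n_replicates + 1):
        for t in design.sample_hours:
            tt = t - t0  # oscillation clock: series starts at first collection
            m_expected = base + amp * np.cos(
                2.0 * np.pi * (tt - (period / 4.0) * phase) / period
            )
            log_ch1 = level0 + m_expected + nsd * rng.standard_normal(n_spots)
            log_ch2 = level0 + nsd * rng.standard_normal(n_spots)
            bg1 = bg_level + np.abs(bg_noise_sd * rng.standard_normal(n_spots))
            bg2 = bg_level + np.abs(bg_noise_sd * rng.standard_normal(n_spots))
            data = pd.DataFrame(
                {
                    "probe_id": spot_pids,
                    "replicate_index": spot_reps,
                    "fg_median_ch1": bg1 + np.exp2(log_ch1),
                    "bg_median_ch1": bg1,
                    "fg_median_ch2": bg2 + np.exp2(log_ch2),
                    "bg_median_ch2": bg2,
                }
            )
            tables.append(SpotTable(float(t), rep, data))
    return tables


# ---------------------------------------------------------------- I/O


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path) -> ArrayLayout:
    return ArrayLayout.from_frame(pd.read_csv(path, sep="\t"))


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    df["is_rhythmic"] = df["is_rhythmic"].astype(bool)
    return df


def write_spot_tables(tables: list[SpotTable], outdir: str | Path) -> list[Path]:
    """One TSV per array, named ``<timepoint>.<replicate>.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tab in tables:
        p = outdir / f"{tab.label}.tsv"
        tab.data.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_spot_tables(indir: str | Path) -> list[SpotTable]:
    tables = []
    for p in sorted(Path(indir).glob("*.tsv")):
        stem = p.stem  # "<hours>.<rep>"
        tp, rep = stem.rsplit(".", 1)
        tables.append(SpotTable(float(tp), int(rep), pd.read_csv(p, sep="\t")))
    return tables
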