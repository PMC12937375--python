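"""Contact persistence statistics: time series → durations → atlas.

The central quantity is the *cumulative duration* of a residue-pair
contact: the total time, within the analysis window, during which the
pair satisfies the geometric criterion, i.e. occupancy × window length.
Durations are aggregated across independent replicas with a fixed
denominator — a replica where a pair never appears contributes 0 ns to
the mean — and reported as mean ± sample SD. The longest continuous
segment is also kept, distinguishing long-lived anchors from an
accumulation of short-lived episodes.

Stated filters: a per-replica occupancy cutoff (keep when the *maximum*
per-replica occupancy reaches the threshold, so contacts stable in a
subset of replicas survive) and an inclusive mean-duration floor, both
composable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import FrameContactSet
from .topology import InteractionLayer, Topology, classify_pair_layer

__all__ = [
    "PairKey",
    "ContactTimeSeries",
    "ReplicaSummary",
    "DurationRecord",
    "DurationAtlas",
    "build_contact_timeseries",
    "summarize_timeseries",
    "aggregate_replicas",
    "filter_atlas",
]


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical residue-pair key: (chain, seq) of both partners plus the
    interaction type, ordered so partner a sorts before partner b."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    itype: str

    @classmethod
    def make(cls, chain_a: str, res_a: int, chain_b: str, res_b: int, itype: str) -> "PairKey":
        if (chain_a, res_a) > (chain_b, res_b):
            chain_a, res_a, chain_b, res_b = chain_b, res_b, chain_a, res_a
        return cls(chain_a, res_a, chain_b, res_b, itype)

    def __str__(self) -> str:
        return f"{self.chain_a}:{self.res_a}--{self.chain_b}:{self.res_b}/{self.itype}"


@dataclass
class ContactTimeSeries:
    """Boolean presence of one (pair, type) per analysis-window frame."""

    key: PairKey
    replica_id: str
    presence: np.ndarray  # bool, length == window frame count
    dt_ns: float

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be > 0")


@dataclass(frozen=True)
class ReplicaSummary:
    cumulative_ns: float
    occupancy: float
    longest_segment_ns: float
    n_segments: int


@dataclass
class DurationRecord:
    key: PairKey
    name_a: str
    name_b: str
    layer: InteractionLayer
    per_replica_duration_ns: list[float]
    per_replica_occupancy: list[float]
    mean_duration_ns: float
    sd_duration_ns: float
    longest_segment_ns: float  # max over replicas
    per_replica_n_segments: list[int] = field(default_factory=list)

    @property
    def max_occupancy(self) -> float:
        return max(self.per_replica_occupancy) if self.per_replica_occupancy else 0.0


@dataclass
class DurationAtlas:
    """All duration records of one complex under one parameter set."""

    label: str
    window_start_ns: float
    window_end_ns: float
    dt_ns: float
    n_replicas: int
    parameters: dict = field(default_factory=dict)
    records: dict[PairKey, DurationRecord] = field(default_factory=dict)
    filters_applied: list[str] = field(default_factory=list)

    @property
    def window_length_ns(self) -> float:
        return self.window_end_ns - self.window_start_ns

    def __post_init__(self) -> None:
        if self.window_length_ns <= 0:
            raise ValueError("window length must be > 0")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.records):
            r = self.records[key]
            row = {
                "complex": self.label,
                "chain_a": key.chain_a,
                "res_a": key.res_a,
                "name_a": r.name_a,
                "chain_b": key.chain_b,
                "res_b": key.res_b,
                "name_b": r.name_b,
                "type": key.itype,
                "layer": f"{r.layer.kind}/{r.layer.span}",
                "mean_ns": r.mean_duration_ns,
                "sd_ns": r.sd_duration_ns,
                "longest_segment_ns": r.longest_segment_ns,
            }
            for i in range(self.n_replicas):
                row[f"occupancy_r{i + 1}"] = r.per_replica_occupancy[i]
            for i in range(self.n_replicas):
                row[f"duration_r{i + 1}_ns"] = r.per_replica_duration_ns[i]
            for i in range(self.n_replicas):
                row[f"n_segments_r{i + 1}"] = (
                    r.per_replica_n_segments[i] if r.per_replica_n_segments else 0
                )
            rows.append(row)
        cols = (
            ["complex", "chain_a", "res_a", "name_a", "chain_b", "res_b", "name_b",
             "type", "layer", "mean_ns", "sd_ns", "longest_segment_ns"]
            + [f"occupancy_r{i + 1}" for i in range(self.n_replicas)]
            + [f"duration_r{i + 1}_ns" for i in range(self.n_replicas)]
            + [f"n_segments_r{i + 1}" for i in range(self.n_replicas)]
        )
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        """Write the atlas TSV plus a JSON provenance sidecar."""
        path = Path(path)
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        sidecar = {
            "complex": self.label,
            "window_start_ns": self.window_start_ns,
            "window_end_ns": self.window_end_ns,
            "dt_ns": self.dt_ns,
            "n_replicas": self.n_replicas,
            "parameters": self.parameters,
            "filters_applied": self.filters_applied,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DurationAtlas":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path, sep="\t")
        atlas = cls(
            label=meta["complex"],
            window_start_ns=meta["window_start_ns"],
            window_end_ns=meta["window_end_ns"],
            dt_ns=meta["dt_ns"],
            n_replicas=meta["n_replicas"],
            parameters=meta.get("parameters", {}),
            filters_applied=meta.get("filters_applied", []),
        )
        n = atlas.n_replicas
        for _, row in df.iterrows():
            key = PairKey.make(
                str(row["chain_a"]), int(row["res_a"]), str(row["chain_b"]),
                int(row["res_b"]), str(row["type"]),
            )
            kind, span = str(row["layer"]).split("/")
            atlas.records[key] = DurationRecord(
                key=key,
                name_a=str(row["name_a"]),
                name_b=str(row["name_b"]),
                layer=InteractionLayer(kind=kind, span=span),
                per_replica_duration_ns=[float(row[f"duration_r{i + 1}_ns"]) for i in range(n)],
                per_replica_occupancy=[float(row[f"occupancy_r{i + 1}"]) for i in range(n)],
                mean_duration_ns=float(row["mean_ns"]),
                sd_duration_ns=float(row["sd_ns"]),
                longest_segment_ns=float(row["longest_segment_ns"]),
                per_replica_n_segments=[
                    int(row.get(f"n_segments_r{i + 1}", 0)) for i in range(n)
                ],
            )
        return atlas


# ---------------------------------------------------------------------------
# operations

def build_contact_timeseries(
    frame_sets: Iterable[FrameContactSet],
    topology: Topology,
    dt_ns: float,
    replica_id: str = "r1",
) -> dict[PairKey, ContactTimeSeries]:
    """Turn one replica's per-frame contact sets into boolean series.

    Only pairs observed in at least one frame get a series; absent pairs
    are implicitly all-false (zero-filled at aggregation).
    """
    present: dict[PairKey, list[int]] = {}
    n_frames = 0
    for pos, fs in enumerate(frame_sets):
        n_frames += 1
        for res_a, res_b, itype in fs.contacts:
            key = _pair_key(topology, res_a, res_b, itype)
            present.setdefault(key, []).append(pos)
    if n_frames == 0:
        raise ValueError("no frames in analysis window: cannot build time series")
    out: dict[PairKey, ContactTimeSeries] = {}
    for key, positions in present.items():
        arr = np.zeros(n_frames, dtype=bool)
        arr[positions] = True
        out[key] = ContactTimeSeries(key=key, replica_id=replica_id, presence=arr, dt_ns=dt_ns)
    return out


def _pair_key(topology: Topology, res_a: int, res_b: int, itype: str) -> PairKey:
    ra, rb = topology.residues[res_a], topology.residues[res_b]
    return PairKey.make(ra.chain_id, ra.seq_number, rb.chain_id, rb.seq_number, itype)


def summarize_timeseries(series: ContactTimeSeries) -> ReplicaSummary:
    """Cumulative duration, occupancy and segment statistics of one series."""
    x = series.presence
    if x.size == 0:
        raise ValueError("empty time series")
    count = int(x.sum())
    cumulative = count * series.dt_ns
    occupancy = count / x.size
    if count == 0:
        return ReplicaSummary(0.0, 0.0, 0.0, 0)
    # maximal runs of True
    padded = np.concatenate(([False], x, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    return ReplicaSummary(
        cumulative_ns=cumulative,
        occupancy=occupancy,
        longest_segment_ns=float(lengths.max()) * series.dt_ns,
        n_segments=int(lengths.size),
    )


def aggregate_replicas(
    summaries: Sequence[Optional[ReplicaSummary]],
    key: PairKey,
    topology: Topology,
    window_length_ns: float,
) -> DurationRecord:
    """Aggregate one pair over ALL replicas, zero-filling absences.

    ``summaries`` has one slot per replica; ``None`` means the pair never
    appeared there and counts as 0 ns / 0 occupancy (fixed denominator).
    SD is the sample SD (ddof=1), defined as 0 for a single replica.
    """
    if not summaries:
        raise ValueError("need at least one replica")
    durations = [s.cumulative_ns if s else 0.0 for s in summaries]
    occupancies = [s.occupancy if s else 0.0 for s in summaries]
    n_segments = [s.n_segments if s else 0 for s in summaries]
    longest = max((s.longest_segment_ns if s else 0.0) for s in summaries)
    mean = float(np.mean(durations))
    sd = float(np.std(durations, ddof=1)) if len(durations) > 1 else 0.0
    ia = topology.residue_index_by_key(key.chain_a, key.res_a)
    ib = topology.residue_index_by_key(key.chain_b, key.res_b)
    layer = classify_pair_layer(topology, ia, ib)
    return DurationRecord(
        key=key,
        name_a=topology.residues[ia].name,
        name_b=topology.residues[ib].name,
        layer=layer,
        per_replica_duration_ns=durations,
        per_replica_occupancy=occupancies,
        mean_duration_ns=mean,
        sd_duration_ns=sd,
        longest_segment_ns=longest,
        per_replica_n_segments=n_segments,
    )


def build_atlas(
    label: str,
    replica_series: Sequence[Mapping[PairKey, ContactTimeSeries]],
    topology: Topology,
    window_start_ns: float,
    window_end_ns: float,
    dt_ns: float,
    parameters: Optional[dict] = None,
) -> DurationAtlas:
    """Assemble the duration atlas from per-replica series collections.

    The result is invariant to replica ordering up to the order of the
    per-replica columns.
    """
    atlas = DurationAtlas(
        label=label,
        window_start_ns=window_start_ns,
        window_end_ns=window_end_ns,
        dt_ns=dt_ns,
        n_replicas=len(replica_series),
        parameters=dict(parameters or {}),
    )
    all_keys: set[PairKey] = set()
    for series in replica_series:
        all_keys |= set(series)
    for key in sorted(all_keys):
        summaries = [
            summarize_timeseries(series[key]) if key in series else None
            for series in replica_series
        ]
        atlas.records[key] = aggregate_replicas(
            summaries, key, topology, atlas.window_length_ns
        )
    return atlas


_FILTER_RULES = ("occupancy_min", "mean_duration_min")


def filter_atlas(atlas: DurationAtlas, rule: str, threshold: float) -> DurationAtlas:
    """Apply a stated filter; returns a new atlas, filters compose.

    ``occupancy_min`` keeps records whose *maximum* per-replica occupancy
    is ≥ threshold (applied before averaging, so a contact stable in one
    replica survives); ``mean_duration_min`` keeps mean duration ≥
    threshold, inclusive. Raising a threshold never increases the record
    count.
    """
    if rule not in _FILTER_RULES:
        raise ValueError(f"unknown filter rule {rule!r}; expected one of {_FILTER_RULES}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if rule == "occupancy_min":
        keep = {k: r for k, r in atlas.records.items() if r.max_occupancy >= threshold}
    else:
        keep = {k: r for k, r in atlas.records.items() if r.mean_duration_ns >= threshold}
    out = DurationAtlas(
        label=atlas.label,
        window_start_ns=atlas.window_start_ns,
        window_end_ns=atlas.window_end_ns,
        dt_ns=atlas.dt_ns,
        n_replicas=atlas.n_replicas,
        parameters=dict(atlas.parameters),
        records=dict(keep),
        filters_applied=atlas.filters_applied + [f"{rule}>={threshold:g}"],
    )
    return out
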