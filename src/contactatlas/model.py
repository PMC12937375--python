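"""Model/Results interface over the contact-persistence pipeline.

`ContactPersistenceModel` is constructed from a topology plus replica
trajectories and an analysis window; `fit()` streams every replica
through geometric contact detection, builds per-pair boolean time
series, and returns a `ContactPersistenceResults` holding the duration
atlas (per-pair mean ± SD cumulative durations, occupancies, longest
segments), with `summary()`, filtering, cross-variant comparison and
heatmap plotting hanging off the results object — the way regression
packages separate model specification from fitted results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .comparison import DifferentialContact, compare_atlases, differential_dataframe
from .contacts import ContactDetector, DetectionParams
from .persistence import (
    ContactTimeSeries,
    DurationAtlas,
    PairKey,
    build_atlas,
    build_contact_timeseries,
    filter_atlas,
)
from .topology import ChemicalRoleTable, Topology, build_role_tables
from .trajectory import ReplicaSet, select_analysis_window

__all__ = ["ContactPersistenceModel", "ContactPersistenceResults"]


class ContactPersistenceModel:
    """Contact-persistence analysis of one complex.

    Parameters
    ----------
    replicas : ReplicaSet
        Topology plus one or more coordinate trajectories with frame→time
        mappings (replicas must share atom ordering).
    window : (float, float)
        Analysis window [start, end) in ns; the default discards the
        first 100 ns of a 1000 ns run, leaving a 900 ns window.
    params : DetectionParams
        Geometric criteria for H-bond / ionic / vdW detection.
    label : str
        Complex label carried into the atlas and every export.
    """

    def __init__(
        self,
        replicas: ReplicaSet,
        window: tuple[float, float] = (100.0, 1000.0),
        params: DetectionParams = DetectionParams(),
        label: str = "complex",
        roles: Optional[ChemicalRoleTable] = None,
    ):
        self.replicas = replicas
        self.topology = replicas.topology
        self.window = window
        self.params = params
        self.label = label
        self.roles = roles if roles is not None else build_role_tables(self.topology)
        if not window[0] < window[1]:
            raise ValueError(f"invalid analysis window {window}")

    @classmethod
    def from_spec(cls, spec, **kwargs) -> "ContactPersistenceModel":
        """Build directly from a synthetic spec (generates the replicas)."""
        from .synthetic import simulate_two_state_contacts

        rs = simulate_two_state_contacts(spec)
        kwargs.setdefault("label", spec.label)
        kwargs.setdefault("window", (100.0, spec.total_time_ns))
        return cls(rs, **kwargs)

    def fit(self, verbose: bool = False) -> "ContactPersistenceResults":
        """Run detection over every replica and aggregate the atlas."""
        detector = ContactDetector(self.topology, self.roles, self.params)
        start, end = self.window
        replica_series: list[dict[PairKey, ContactTimeSeries]] = []
        frame_counts: list[int] = []
        contact_counts: list[int] = []
        for rep in self.replicas.replicas:
            frames = select_analysis_window(rep.iter_frames(self.topology), start, end)
            frame_sets = []
            n_contacts = 0
            for f in frames:
                fs = detector.detect_all(f)
                n_contacts += len(fs)
                frame_sets.append(fs)
            series = build_contact_timeseries(
                frame_sets, self.topology, rep.mapping.dt_ns, rep.replica_id
            )
            replica_series.append(series)
            frame_counts.append(len(frame_sets))
            contact_counts.append(n_contacts)
            if verbose:
                print(
                    f"[{self.label}] replica {rep.replica_id}: "
                    f"{len(frame_sets)} frames, {n_contacts} contact-frames, "
                    f"{len(series)} pairs"
                )
        parameters = {
            **self.params.as_dict(),
            "implicit_hydrogens": self.roles.implicit_hydrogens,
            "window_start_ns": start,
            "window_end_ns": end,
        }
        atlas = build_atlas(
            self.label,
            replica_series,
            self.topology,
            start,
            end,
            self.replicas.replicas[0].mapping.dt_ns,
            parameters,
        )
        return ContactPersistenceResults(
            model=self,
            atlas=atlas,
            frame_counts=frame_counts,
            contact_counts=contact_counts,
        )


@dataclass
class ContactPersistenceResults:
    """Fitted contact-persistence atlas plus bookkeeping diagnostics."""

    model: ContactPersistenceModel
    atlas: DurationAtlas
    frame_counts: list[int] = field(default_factory=list)
    contact_counts: list[int] = field(default_factory=list)

    # -- views ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return self.atlas.to_dataframe()

    def filter(self, rule: str, threshold: float) -> "ContactPersistenceResults":
        """Stated filters: ``occupancy_min`` (max per-replica occupancy) or
        ``mean_duration_min`` (inclusive); returns new results, composable."""
        return ContactPersistenceResults(
            model=self.model,
            atlas=filter_atlas(self.atlas, rule, threshold),
            frame_counts=self.frame_counts,
            contact_counts=self.contact_counts,
        )

    def compare(
        self, other: "ContactPersistenceResults | DurationAtlas", alpha: float = 0.05
    ) -> list[DifferentialContact]:
        other_atlas = other.atlas if isinstance(other, ContactPersistenceResults) else other
        return compare_atlases(self.atlas, other_atlas, alpha=alpha)

    def compare_frame(self, other, alpha: float = 0.05) -> pd.DataFrame:
        return differential_dataframe(self.compare(other, alpha=alpha))

    def summary(self, top: int = 15) -> str:
        """Human-readable fit summary, statsmodels-style."""
        a = self.atlas
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Contact Persistence Atlas".center(w))
        lines.append("=" * w)
        lines.append(f"Complex:            {a.label}")
        lines.append(f"Replicas:           {a.n_replicas}")
        lines.append(
            f"Window:             [{a.window_start_ns:g}, {a.window_end_ns:g}) ns "
            f"({a.window_length_ns:g} ns)"
        )
        lines.append(f"Frames analysed:    {self.frame_counts} (dt = {a.dt_ns:g} ns)")
        lines.append(f"Contact records:    {len(a.records)}")
        if a.filters_applied:
            lines.append(f"Filters:            {', '.join(a.filters_applied)}")
        det = {k: v for k, v in a.parameters.items() if not k.startswith("window")}
        lines.append(f"Detection:          {det}")
        lines.append("-" * w)
        lines.append(
            f"{'pair':<30}{'type':<7}{'layer':<26}{'mean±SD ns':>9}"
        )
        lines.append("-" * w)
        records = sorted(
            a.records.values(), key=lambda r: -r.mean_duration_ns
        )[:top]
        for r in records:
            pair = f"{r.key.chain_a}:{r.name_a}{r.key.res_a}–{r.key.chain_b}:{r.name_b}{r.key.res_b}"
            lines.append(
                f"{pair:<30}{r.key.itype:<7}{r.layer.kind + '/' + r.layer.span:<26}"
                f"{r.mean_duration_ns:7.1f}±{r.sd_duration_ns:<.1f}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    # -- bookkeeping ------------------------------------------------------
    def total_presences(self) -> int:
        """Σ over pairs of per-frame presences; equals Σ over frames of the
        per-frame contact count (bookkeeping identity)."""
        return int(sum(self.contact_counts))

    # -- export -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.atlas.to_tsv(path)

    def plot_heatmap(self, chain_pair: tuple[str, str], itype: str, ax=None, **kwargs):
        from .reporting import build_duration_matrix, plot_heatmap

        matrix = build_duration_matrix(self.atlas, chain_pair, itype)
        return plot_heatmap(matrix, ax=ax, **kwargs)
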