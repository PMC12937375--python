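"""Heatmap matrices, report bundles and the pipeline driver.

The data layer and the rendering layer are separated: heatmap cell
values are exactly the atlas mean cumulative durations (no rescaling),
figures are regenerable from the exported TSVs alone, and every output
references a provenance JSON recording thresholds, parameters and
seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .comparison import compare_atlases, differential_dataframe
from .contacts import DetectionParams, HBondParams, IonicParams, VdwParams
from .metrics import backbone_selection, convergence_series, glycan_c1_selection, rmsf
from .model import ContactPersistenceModel
from .persistence import DurationAtlas, filter_atlas
from .topology import build_topology, classify_residues
from .trajectory import Replica, ReplicaSet, TimeMapping

__all__ = ["HeatmapMatrix", "RunConfig", "build_duration_matrix", "plot_heatmap", "run_pipeline"]

logger = logging.getLogger("contactatlas")


@dataclass
class HeatmapMatrix:
    """Dense mean-duration matrix for one chain pair and interaction type.

    Rows are residues of the first chain, columns of the second, both
    ordered by author residue number; absent cells are 0; values are the
    atlas mean cumulative durations in ns, bounded by the window length.
    """

    chain_a: str
    chain_b: str
    itype: str
    values: pd.DataFrame  # rows: chain_a residues, cols: chain_b residues
    display_min_ns: float
    window_length_ns: float

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < 0 or v.max() > self.window_length_ns + 1e-9):
            raise ValueError("heatmap cells must lie in [0, window_length_ns]")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate heatmap labels")


def build_duration_matrix(
    atlas: DurationAtlas,
    chain_pair: tuple[str, str],
    itype: str,
    display_min_ns: float = 0.0,
) -> HeatmapMatrix:
    """Matrix over residues appearing in ≥1 record surviving the display
    floor; empty atlas selections yield an empty matrix with a warning."""
    if display_min_ns > 0:
        atlas = filter_atlas(atlas, "mean_duration_min", display_min_ns)
    ca, cb = chain_pair
    cells: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    for key, rec in atlas.records.items():
        if key.itype != itype:
            continue
        if key.chain_a == ca and key.chain_b == cb:
            row = (key.res_a, rec.name_a)
            col = (key.res_b, rec.name_b)
        elif key.chain_a == cb and key.chain_b == ca:
            row = (key.res_b, rec.name_b)
            col = (key.res_a, rec.name_a)
        else:
            continue
        cells[(row, col)] = rec.mean_duration_ns
    if not cells:
        import warnings

        warnings.warn(
            f"no {itype} records for chain pair {ca}×{cb} above {display_min_ns} ns",
            stacklevel=2,
        )
        values = pd.DataFrame()
    else:
        rows = sorted({r for r, _ in cells})
        cols = sorted({c for _, c in cells})
        values = pd.DataFrame(
            0.0,
            index=[f"{name}{seq}" for seq, name in rows],
            columns=[f"{name}{seq}" for seq, name in cols],
        )
        for (r, c), v in cells.items():
            values.loc[f"{r[1]}{r[0]}", f"{c[1]}{c[0]}"] = v
    return HeatmapMatrix(
        chain_a=ca,
        chain_b=cb,
        itype=itype,
        values=values,
        display_min_ns=display_min_ns,
        window_length_ns=atlas.window_length_ns,
    )


def plot_heatmap(matrix: HeatmapMatrix, ax=None, cmap: str = "YlOrRd", **kwargs):
    """Render a duration matrix; colour mapping spans [0, window length]."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(matrix.values.columns) + 2),
                                      max(3, 0.4 * len(matrix.values.index) + 2)))
    sns.heatmap(
        matrix.values,
        ax=ax,
        vmin=0.0,
        vmax=matrix.window_length_ns,
        cmap=cmap,
        cbar_kws={"label": "mean cumulative duration (ns)"},
        **kwargs,
    )
    ax.set_xlabel(f"chain {matrix.chain_b}")
    ax.set_ylabel(f"chain {matrix.chain_a}")
    ax.set_title(f"{matrix.itype} durations, {matrix.chain_a}×{matrix.chain_b}")
    return ax


# ---------------------------------------------------------------------------
# run configuration

_REQUIRED_COMPLEX_KEYS = ("label", "topology", "replicas", "dt_ns")


@dataclass
class RunConfig:
    """Declarative pipeline configuration (schema-validated on load)."""

    complexes: list[dict]
    output_dir: str
    window_start_ns: float = 100.0
    window_end_ns: float = 1000.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    occupancy_min: float = 0.10
    display_min_ns: float = 45.0
    persistent_min_ns: float = 200.0
    alpha: float = 0.05
    seed: int = 0
    make_figures: bool = True

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        missing = [k for k in ("complexes", "output_dir") if k not in raw]
        if missing:
            raise ValueError(f"config missing required key(s): {missing}")
        complexes = raw["complexes"]
        if not complexes:
            raise ValueError("config lists no complexes")
        for i, c in enumerate(complexes):
            for k in _REQUIRED_COMPLEX_KEYS:
                if k not in c:
                    raise ValueError(f"complex #{i + 1} missing required key {k!r}")
            if not c["replicas"]:
                raise ValueError(f"complex {c['label']!r} lists no replicas")
        det_raw = dict(raw.get("detection", {}))
        detection = DetectionParams(
            hbond=HBondParams(
                max_da_dist_A=det_raw.get("hbond_max_da_dist_A", 3.5),
                min_dha_angle_deg=det_raw.get("hbond_min_dha_angle_deg", 120.0),
            ),
            ionic=IonicParams(max_group_dist_A=det_raw.get("ionic_max_group_dist_A", 4.0)),
            vdw=VdwParams(radius_slack_A=det_raw.get("vdw_radius_slack_A", 0.5)),
        )
        return cls(
            complexes=list(complexes),
            output_dir=str(raw["output_dir"]),
            window_start_ns=float(raw.get("window_start_ns", 100.0)),
            window_end_ns=float(raw.get("window_end_ns", 1000.0)),
            detection=detection,
            occupancy_min=float(raw.get("occupancy_min", 0.10)),
            display_min_ns=float(raw.get("display_min_ns", 45.0)),
            persistent_min_ns=float(raw.get("persistent_min_ns", 200.0)),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
            make_figures=bool(raw.get("make_figures", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    def provenance(self) -> dict:
        from . import __version__

        return {
            "package": "contactatlas",
            "version": __version__,
            "seed": self.seed,
            "window_start_ns": self.window_start_ns,
            "window_end_ns": self.window_end_ns,
            "detection": self.detection.as_dict(),
            "occupancy_min": self.occupancy_min,
            "display_min_ns": self.display_min_ns,
            "persistent_min_ns": self.persistent_min_ns,
            "alpha": self.alpha,
            "complexes": [
                {"label": c["label"], "topology": str(c["topology"]),
                 "replicas": [str(r) for r in c["replicas"]],
                 "dt_ns": c["dt_ns"], "t0_ns": c.get("t0_ns", 0.0)}
                for c in self.complexes
            ],
        }


# ---------------------------------------------------------------------------
# pipeline driver

def run_pipeline(config: RunConfig) -> dict:
    """Execute load → window → detect → persist → filter → compare →
    metrics → export; returns a path map of the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = config.provenance()
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")

    bundle: dict = {"provenance": str(out / "provenance.json"), "complexes": {}}
    fitted: dict[str, Any] = {}
    for cfg in config.complexes:
        label = cfg["label"]
        logger.info("stage=load complex=%s topology=%s", label, cfg["topology"])
        topo = build_topology(cfg["topology"])
        classify_residues(topo)
        mapping = TimeMapping(dt_ns=float(cfg["dt_ns"]), t0_ns=float(cfg.get("t0_ns", 0.0)))
        replicas = ReplicaSet(
            topology=topo,
            replicas=[
                Replica(replica_id=f"r{i + 1}", source=str(p), mapping=mapping)
                for i, p in enumerate(cfg["replicas"])
            ],
        )
        model = ContactPersistenceModel(
            replicas,
            window=(config.window_start_ns, config.window_end_ns),
            params=config.detection,
            label=label,
        )
        res = model.fit()
        logger.info(
            "stage=detect complex=%s frames=%s presences=%d pairs=%d",
            label, res.frame_counts, res.total_presences(), len(res.atlas),
        )
        res_occ = res.filter("occupancy_min", config.occupancy_min)
        logger.info(
            "stage=filter complex=%s rule=occupancy_min>=%.2f records=%d",
            label, config.occupancy_min, len(res_occ.atlas),
        )
        cdir = out / label
        cdir.mkdir(exist_ok=True)
        res_occ.to_tsv(cdir / "atlas.tsv")
        persistent = filter_atlas(res_occ.atlas, "mean_duration_min", config.persistent_min_ns)
        persistent.to_tsv(cdir / "persistent_contacts.tsv")
        paths = {
            "atlas": str(cdir / "atlas.tsv"),
            "persistent": str(cdir / "persistent_contacts.tsv"),
        }

        # figures from the display-floored atlas
        if config.make_figures:
            shown = filter_atlas(res_occ.atlas, "mean_duration_min", config.display_min_ns)
            chain_pairs = sorted(
                {(k.chain_a, k.chain_b, k.itype) for k in shown.records}
            )
            import matplotlib

            matplotlib.use("Agg", force=True)
            import matplotlib.pyplot as plt

            figures = []
            for ca, cb, itype in chain_pairs:
                m = build_duration_matrix(shown, (ca, cb), itype)
                if m.values.empty:
                    continue
                ax = plot_heatmap(m)
                fig_path = cdir / f"heatmap_{ca}_{cb}_{itype}.png"
                ax.figure.savefig(fig_path, dpi=120, bbox_inches="tight")
                plt.close(ax.figure)
                figures.append(str(fig_path))
            paths["figures"] = figures

        # metrics: second pass over frames for RMSF / convergence
        paths.update(_export_metrics(cdir, topo, replicas, config))
        logger.info("stage=metrics complex=%s", label)
        fitted[label] = res_occ
        bundle["complexes"][label] = paths

    labels = list(fitted)
    if len(labels) >= 2:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                diffs = compare_atlases(fitted[a].atlas, fitted[b].atlas, alpha=config.alpha)
                df = differential_dataframe(diffs)
                p = out / f"differential_{a}_vs_{b}.tsv"
                df.to_csv(p, sep="\t", index=False, float_format="%.6f")
                n_sig = int(df["significant"].sum())
                logger.info(
                    "stage=compare a=%s b=%s tests=%d significant=%d",
                    a, b, int(df["status"].eq("shared").sum()), n_sig,
                )
                bundle.setdefault("differentials", []).append(str(p))
    return bundle


def _export_metrics(cdir: Path, topo, replicas: ReplicaSet, config: RunConfig) -> dict:
    fit_sel = backbone_selection(topo)
    c1_sel, c1_meta = glycan_c1_selection(topo)
    paths: dict = {}
    rows = []
    conv_rows = []
    for rep in replicas.replicas:
        from .trajectory import select_analysis_window

        if len(c1_sel):
            frames = select_analysis_window(
                rep.iter_frames(topo), config.window_start_ns, config.window_end_ns
            )
            prof = rmsf(frames, c1_sel, fit_selection=fit_sel, label="glycan-C1")
            for meta, val in zip(c1_meta, prof.rmsf_A):
                rows.append({**meta, "atom": "C1", "rmsf_A": val, "replica": rep.replica_id})
        frames = select_analysis_window(
            rep.iter_frames(topo), config.window_start_ns, config.window_end_ns
        )
        conv = convergence_series(frames, fit_sel, topology=topo)
        conv_rows.append(
            {
                "replica": rep.replica_id,
                "mean_rmsd_A": float(np.mean(conv.rmsd_A)),
                "max_rmsd_A": float(np.max(conv.rmsd_A)),
                "mean_rg_A": float(np.mean(conv.rg_A)),
            }
        )
    if rows:
        df = pd.DataFrame(rows)
        mean_df = (
            df.groupby(["chain", "residue", "name", "anchor", "glycan_position", "atom"],
                       as_index=False)["rmsf_A"]
            .agg(["mean", "std"])
            .reset_index()
        )
        df.to_csv(cdir / "glycan_c1_rmsf.tsv", sep="\t", index=False, float_format="%.6f")
        paths["glycan_c1_rmsf"] = str(cdir / "glycan_c1_rmsf.tsv")
    pd.DataFrame(conv_rows).to_csv(
        cdir / "convergence.tsv", sep="\t", index=False, float_format="%.6f"
    )
    paths["convergence"] = str(cdir / "convergence.tsv")
    return paths
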