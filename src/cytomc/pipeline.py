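"""End-to-end pipeline orchestration.

Stages write their outputs as plain files under one working directory and
read their predecessors' files back, so any stage can be re-run in
isolation after deleting its downstream outputs.  All randomness derives
from the single root seed via fixed per-stage offsets.

Stage order: simulate/ingest -> preprocess -> cluster -> metacluster ->
entropy -> typing -> cooccur -> report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality as clonality_mod
from . import cooccurrence as cooc_mod
from .clustering import consensus_cluster, prune_rare_clusters, subsample_per_sample
from .core import ARCSINH, CellTable, MarkerPanel, ValidationError
from .entropy import intersample_entropy, per_sample_intratumoral_entropy
from .metacluster import assign_metaclusters, cluster_medians, fit_metaclusters, rank_markers
from .preprocess import preprocess_pipeline
from .synthetic import example_cohort_config, read_cohort, simulate_cohort, write_cohort

log = logging.getLogger("cytomc.pipeline")

SEED_SUBSAMPLE = 1000
SEED_CLUSTER = 2000
SEED_GAP = 3000


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    simulate: dict | None = None       # kwargs for example_cohort_config
    input_dir: str | None = None       # pre-existing cohort directory
    cofactor_a: float = 0.2
    norm_scale: str = "raw"
    k_neighbors: int = 20
    runs: int = 5
    min_cluster_fraction: float = 0.01
    max_cells_per_sample: int | None = None
    k_metaclusters: int | None = None  # None -> gap statistic
    k_max: int | None = None
    gap_B: int = 50
    clonality_min_cells: int = 20
    typing_rule: str = clonality_mod.RULE_MOST_ABUNDANT
    presence_threshold: float = 0.01
    alpha: float = 0.05
    nmi_variant: str = "sqrt"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one of 'simulate' and 'input_dir' must be given"
            )
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValidationError(f"input_dir does not exist: {self.input_dir}")
        if self.runs < 2:
            raise ValidationError("runs must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


# ---------------------------------------------------------------------------
# file-level helpers
# ---------------------------------------------------------------------------

def _panel_to_json(panel: MarkerPanel, path: Path) -> None:
    path.write_text(
        json.dumps(
            {
                "marker_names": list(panel.marker_names),
                "kappa_index": panel.kappa_index,
                "lambda_index": panel.lambda_index,
                "clustering_mask": [bool(b) for b in panel.clustering_mask],
            }
        )
    )


def _panel_from_json(path: Path) -> MarkerPanel:
    d = json.loads(path.read_text())
    return MarkerPanel(
        tuple(d["marker_names"]),
        d["kappa_index"],
        d["lambda_index"],
        tuple(d["clustering_mask"]),
    )


def _read_preprocessed(workdir: Path) -> tuple[CellTable, MarkerPanel]:
    cells = CellTable.read_csv(workdir / "preprocessed" / "cells.csv", scale=ARCSINH)
    panel = _panel_from_json(workdir / "preprocessed" / "panel.json")
    return cells, panel


def _read_labels(workdir: Path) -> pd.DataFrame:
    return pd.read_csv(workdir / "cluster" / "labels.csv")


def _timed(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.monotonic()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", name, time.monotonic() - self.t0)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, workdir: Path) -> Path:
    """Generate (or locate) the input cohort directory."""
    if cfg.input_dir is not None:
        return Path(cfg.input_dir)
    with _timed("simulate"):
        cohort = simulate_cohort(example_cohort_config(**cfg.simulate, seed=cfg.seed))
        out = workdir / "cohort"
        write_cohort(cohort, out)
    return out


def stage_preprocess(cfg: PipelineConfig, workdir: Path, cohort_dir: Path) -> None:
    with _timed("preprocess"):
        cells, panel, truth = read_cohort(cohort_dir)
        cells, panel_kl, factors = preprocess_pipeline(
            cells, None, panel, scale_a=cfg.cofactor_a, norm_scale=cfg.norm_scale
        )
        out = workdir / "preprocessed"
        out.mkdir(parents=True, exist_ok=True)
        cells.write_csv(out / "cells.csv")
        _panel_to_json(panel_kl, out / "panel.json")
        factors.write_json(out / "factors.json")
        if truth is not None:
            truth.to_json(out / "sample_truth.json", orient="records")


def stage_cluster(cfg: PipelineConfig, workdir: Path) -> None:
    with _timed("cluster"):
        cells, panel = _read_preprocessed(workdir)
        analysis = cells.subset(~cells.is_control)
        if cfg.max_cells_per_sample:
            keep = subsample_per_sample(
                analysis.sample_id, cfg.max_cells_per_sample, seed=cfg.seed + SEED_SUBSAMPLE
            )
            analysis = analysis.subset(keep)
        X = analysis.matrix(panel.clustering_markers)
        k = min(cfg.k_neighbors, analysis.n_cells - 1)
        if k < cfg.k_neighbors:
            log.warning("k_neighbors reduced to %d for %d cells", k, analysis.n_cells)
        result = consensus_cluster(
            X, k, R=cfg.runs, seed=cfg.seed + SEED_CLUSTER, nmi_variant=cfg.nmi_variant
        )
        retained = prune_rare_clusters(
            result.labels, analysis.sample_id, cfg.min_cluster_fraction
        )
        out = workdir / "cluster"
        out.mkdir(parents=True, exist_ok=True)
        df = analysis.to_dataframe()[["sample_id", "batch_id"]]
        df.insert(0, "cell_id", np.arange(analysis.n_cells))
        df["cluster"] = result.labels
        df["retained"] = retained.astype(int)
        for r, run in enumerate(result.runs):
            df[f"run{r}"] = run.labels
        df.to_csv(out / "labels.csv", index=False)
        analysis.write_csv(out / "cells.csv")
        (out / "consensus.json").write_text(
            json.dumps(
                {
                    "selected": result.selected,
                    "mean_ari": result.mean_ari,
                    "mean_nmi": result.mean_nmi,
                    "ari": result.ari.tolist(),
                    "nmi": result.nmi.tolist(),
                    "modularity": [r.modularity for r in result.runs],
                },
                indent=2,
            )
        )


def _read_clustered(workdir: Path) -> tuple[CellTable, MarkerPanel, pd.DataFrame]:
    cells = CellTable.read_csv(workdir / "cluster" / "cells.csv", scale=ARCSINH)
    panel = _panel_from_json(workdir / "preprocessed" / "panel.json")
    labels = _read_labels(workdir)
    return cells, panel, labels


def stage_metacluster(cfg: PipelineConfig, workdir: Path) -> None:
    with _timed("metacluster"):
        cells, panel, labels = _read_clustered(workdir)
        retained = labels["retained"].to_numpy(dtype=bool)
        lab = labels["cluster"].to_numpy()
        sub = cells.subset(retained)
        medians_all = cluster_medians(sub.values, lab[retained])
        medians_all.columns = list(cells.marker_names)
        cidx = [cells.marker_index(m) for m in panel.clustering_markers]
        n_clusters = medians_all.shape[0]
        k = cfg.k_metaclusters
        curve = None
        if k is None and n_clusters > 1:
            # Select k with the gap statistic evaluated on a cell subsample
            # (many points per candidate metacluster); the median-profile
            # matrix has too few rows for a meaningful reference
            # distribution.  Chosen k is clamped to the cluster count; in
            # high-dimensional marker space the 1-SE rule is conservative
            # about merging, which can only over-split metaclusters.
            rng = np.random.default_rng(cfg.seed + SEED_GAP)
            n_gap = min(800, sub.n_cells)
            idx = rng.choice(sub.n_cells, n_gap, replace=False)
            Xg = sub.values[np.sort(idx)][:, cidx]
            k_max = min(cfg.k_max or n_clusters, n_clusters, n_gap - 1)
            from .metacluster import gap_statistic

            curve = gap_statistic(
                Xg, k_max=k_max, B=cfg.gap_B, seed=cfg.seed + SEED_GAP
            )
            k = min(curve.chosen_k, n_clusters)
        elif k is None:
            k = 1
        model = fit_metaclusters(medians_all.iloc[:, cidx], k=k)
        if curve is not None:
            model.gap_curve = curve
        out = workdir / "metacluster"
        out.mkdir(parents=True, exist_ok=True)
        medians_all.to_csv(out / "medians.csv")
        pd.DataFrame(
            {"cluster": list(model.mc_map), "metacluster": list(model.mc_map.values())}
        ).to_csv(out / "mc_map.csv", index=False)
        if model.gap_curve is not None:
            model.gap_curve.to_frame().to_csv(out / "gap_curve.csv", index=False)
        (out / "model.json").write_text(json.dumps({"chosen_k": model.chosen_k}))
        mc = assign_metaclusters(model, lab[retained])
        mc_col = np.full(len(labels), -1, dtype=int)
        mc_col[retained] = mc
        labels["metacluster"] = mc_col
        labels.to_csv(workdir / "cluster" / "labels.csv", index=False)


def stage_entropy(cfg: PipelineConfig, workdir: Path) -> None:
    with _timed("entropy"):
        cells, panel, labels = _read_clustered(workdir)
        retained = labels["retained"].to_numpy(dtype=bool)
        sub = cells.subset(retained)
        X = sub.matrix(panel.clustering_markers)
        ent = intersample_entropy(X, sub.sample_id)
        out = workdir / "entropy"
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "cell_id": labels.loc[retained, "cell_id"].to_numpy(),
                "sample_id": sub.sample_id,
                "intersample_entropy": ent,
            }
        ).to_csv(out / "intersample.csv", index=False)


def stage_typing(cfg: PipelineConfig, workdir: Path) -> None:
    with _timed("typing"):
        cells, panel, labels = _read_clustered(workdir)
        retained = labels["retained"].to_numpy(dtype=bool)
        lab = labels["cluster"].to_numpy()
        mc = labels["metacluster"].to_numpy()
        sub = cells.subset(retained)
        sub_lab = lab[retained]
        sub_mc = mc[retained]

        calls = clonality_mod.call_clonality(
            sub, sub_lab, panel, min_cells=cfg.clonality_min_cells
        )
        # clusters whose cohort-wide profile matches a normal template are not
        # annotated automatically; an Ab map can be supplied externally.
        calls = clonality_mod.flag_abnormal(calls, {})
        clonal = clonality_mod.clonal_cell_mask(sub, sub_lab, calls)

        mc_counts_total = pd.Series(sub_mc[clonal]).value_counts()
        medians = pd.read_csv(workdir / "metacluster" / "medians.csv", index_col=0)
        mc_map = pd.read_csv(workdir / "metacluster" / "mc_map.csv").set_index("cluster")[
            "metacluster"
        ]
        mc_medians = medians.groupby(mc_map).median()
        if len(mc_counts_total):
            mc_a, mc_b = clonality_mod.designate_ab_metaclusters(
                mc_medians, mc_counts_total, tuple(medians.columns)
            )
        else:  # no clonal cells anywhere (pure rLN cohort)
            mc_a = mc_b = None

        types = []
        for rule in (clonality_mod.RULE_MOST_ABUNDANT, clonality_mod.RULE_MAJORITY_50):
            for s in pd.unique(sub.sample_id):
                m = sub.sample_id == s
                counts = pd.Series(sub_mc[m & clonal]).value_counts()
                types.append(
                    clonality_mod.assign_tumor_type(
                        s, counts, int(m.sum()), mc_a, mc_b, rule=rule
                    )
                )
        out = workdir / "typing"
        out.mkdir(parents=True, exist_ok=True)
        clonality_mod.clonality_table(calls).to_csv(out / "clonality.csv", index=False)
        clonality_mod.typing_table(types).to_csv(out / "typing.csv", index=False)
        (out / "mc_designation.json").write_text(
            json.dumps(
                {
                    "mc_a": None if mc_a is None else int(mc_a),
                    "mc_b": None if mc_b is None else int(mc_b),
                }
            )
        )
        ent = per_sample_intratumoral_entropy(sub.sample_id, sub_lab, clonal)
        ent.rename_axis("sample_id").reset_index().to_csv(
            out / "intratumoral_entropy.csv", index=False
        )
        pd.DataFrame(
            {"cell_id": labels.loc[retained, "cell_id"].to_numpy(), "clonal": clonal.astype(int)}
        ).to_csv(out / "clonal_cells.csv", index=False)


def stage_cooccur(cfg: PipelineConfig, workdir: Path) -> None:
    with _timed("cooccur"):
        cells, panel, labels = _read_clustered(workdir)
        retained = labels["retained"].to_numpy(dtype=bool)
        mc = labels["metacluster"].to_numpy()[retained]
        sub = cells.subset(retained)
        clonal = (
            pd.read_csv(workdir / "typing" / "clonal_cells.csv")["clonal"]
            .to_numpy(dtype=bool)
        )
        desig = json.loads((workdir / "typing" / "mc_designation.json").read_text())

        comp = cooc_mod.composition_matrix(sub.sample_id, mc, denominator_mask=clonal)
        presence = cooc_mod.presence_matrix(comp, cfg.presence_threshold)
        result = cooc_mod.cooccurrence_analysis(presence, alpha=cfg.alpha)
        out = workdir / "cooccur"
        out.mkdir(parents=True, exist_ok=True)
        comp.to_csv(out / "composition.csv")
        presence.to_csv(out / "presence.csv")
        result.to_frame().to_csv(out / "cooccurrence.csv", index=False)
        cooc_mod.export_network(result, out / "network.graphml", out / "network_edges.tsv")

        chi2_payload = None
        mc_a, mc_b = desig["mc_a"], desig["mc_b"]
        if mc_b is not None and mc_a in presence.columns and mc_b in presence.columns:
            try:
                stat, p = cooc_mod.exclusivity_chi2(
                    presence[mc_a].to_numpy(), presence[mc_b].to_numpy()
                )
                chi2_payload = {"chi2": stat, "p": p}
            except ValidationError as exc:
                chi2_payload = {"error": str(exc)}
        (out / "exclusivity.json").write_text(json.dumps({"mc_a_vs_mc_b": chi2_payload}))

        if comp.shape[0] >= 3:
            _, groups = cooc_mod.jsd_cluster_samples(comp)
            groups.rename_axis("sample_id").reset_index().to_csv(
                out / "jsd_groups.csv", index=False
            )


def stage_report(cfg: PipelineConfig, workdir: Path) -> dict:
    with _timed("report"):
        typing = pd.read_csv(workdir / "typing" / "typing.csv")
        primary = typing[typing["rule"] == cfg.typing_rule].set_index("sample_id")
        intratumoral = pd.read_csv(workdir / "typing" / "intratumoral_entropy.csv").set_index(
            "sample_id"
        )
        consensus = json.loads((workdir / "cluster" / "consensus.json").read_text())
        desig = json.loads((workdir / "typing" / "mc_designation.json").read_text())
        model = json.loads((workdir / "metacluster" / "model.json").read_text())
        exclusivity = json.loads((workdir / "cooccur" / "exclusivity.json").read_text())
        labels = _read_labels(workdir)
        n_clusters = int(labels.loc[labels["retained"] == 1, "cluster"].nunique())

        samples = {}
        for s, row in primary.iterrows():
            ent = intratumoral["intratumoral_entropy"].get(s)
            samples[str(s)] = {
                "type": row["type"],
                "clonal_fraction": float(row["clonal_fraction"]),
                "dominant_mc": None
                if pd.isna(row["dominant_mc"])
                else int(row["dominant_mc"]),
                "intratumoral_entropy": None if pd.isna(ent) else float(ent),
            }

        ranking_payload = None
        truth_payload = None
        truth_path = workdir / "preprocessed" / "sample_truth.json"
        if truth_path.exists():
            truth = pd.read_json(truth_path).set_index("sample_id")
            agree = 0
            comparable = 0
            for s, row in primary.iterrows():
                if s not in truth.index:
                    continue
                comparable += 1
                planted = truth.loc[s, "type"]
                got = row["type"]
                if (planted == "rLN" and got == "rLN-like") or planted == got:
                    agree += 1
            truth_payload = {
                "n_compared": comparable,
                "n_agree": agree,
                "agreement": agree / comparable if comparable else None,
            }

        try:
            ranking_payload = _marker_ranking_payload(cfg, workdir, primary)
        except (ValidationError, FileNotFoundError) as exc:
            log.info("marker ranking skipped: %s", exc)

        report = {
            "config": {
                "seed": cfg.seed,
                "typing_rule": cfg.typing_rule,
                "k_neighbors": cfg.k_neighbors,
                "runs": cfg.runs,
            },
            "cohort": {
                "n_samples": int(primary.shape[0]),
                "n_clusters": n_clusters,
                "n_metaclusters": model["chosen_k"],
                "mc_a": desig["mc_a"],
                "mc_b": desig["mc_b"],
                "consensus_mean_ari": consensus["mean_ari"],
                "consensus_mean_nmi": consensus["mean_nmi"],
                "exclusivity": exclusivity["mc_a_vs_mc_b"],
                "marker_ranking": ranking_payload,
                "truth_agreement": truth_payload,
            },
            "samples": samples,
        }
        (workdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _marker_ranking_payload(cfg: PipelineConfig, workdir: Path, primary: pd.DataFrame):
    cells = CellTable.read_csv(workdir / "cluster" / "cells.csv", scale=ARCSINH)
    labels = _read_labels(workdir)
    retained = labels["retained"].to_numpy(dtype=bool)
    sub = cells.subset(retained)
    clonal = pd.read_csv(workdir / "typing" / "clonal_cells.csv")["clonal"].to_numpy(dtype=bool)
    rows, idx = [], []
    for s in pd.unique(sub.sample_id):
        m = (sub.sample_id == s) & clonal
        if m.sum() == 0:
            continue
        rows.append(np.median(sub.values[m], axis=0))
        idx.append(s)
    profiles = pd.DataFrame(rows, index=idx, columns=list(sub.marker_names))
    types = primary.loc[profiles.index, "type"]
    ranking = rank_markers(profiles, types)
    ranking.to_frame().to_csv(workdir / "typing" / "marker_ranking.csv", index=False)
    m98 = int(np.searchsorted(ranking.cumulative_share, 0.98) + 1)
    return {
        "top_markers": ranking.order[:10],
        "markers_for_98pct": m98,
        "n_markers": len(ranking.order),
    }


def run_pipeline(cfg: PipelineConfig, workdir: str | Path) -> dict:
    """Run every stage in order; returns the report dict."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cohort_dir = stage_simulate(cfg, workdir)
    stage_preprocess(cfg, workdir, cohort_dir)
    stage_cluster(cfg, workdir)
    stage_metacluster(cfg, workdir)
    stage_entropy(cfg, workdir)
    stage_typing(cfg, workdir)
    stage_cooccur(cfg, workdir)
    return stage_report(cfg, workdir)
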