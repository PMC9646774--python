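"""Synthetic multi-sample, multi-batch cytometry cohorts.

Generates cohorts with planted population structure so every downstream
stage (normalization, clustering, metaclustering, entropy, clonality typing,
co-occurrence) can be exercised without access-restricted data.  Cells are
drawn per population template as Gaussians on the arcsinh scale, mapped to
the raw scale by ``sinh`` (truncated at zero), mixed across channels by a
linear spillover matrix, and finally multiplied by per-batch per-channel
gain factors.  Each batch carries one pooled-control aliquot drawn from a
fixed mixture shared across batches, which makes the batch gains exactly
identifiable from control medians.

Template means are synthetic defaults chosen only to realize the documented
phenotype contrasts (GCB-like clones: IgG/HLA-DR/CD22-high; memory-like
clones: IgM/CD79B/CD24/CD44-high); no real-panel distributions are implied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CellTable, MarkerPanel, ValidationError, concat_tables
from .preprocess import DEFAULT_SCALE_A, SpilloverMatrix

POLYTYPIC = "polytypic"
KAPPA = "kappa"
LAMBDA = "lambda"
LIGHT_CHAINS = (POLYTYPIC, KAPPA, LAMBDA)

NORMAL_KINDS = ("normal-naive", "normal-memory", "normal-GC", "normal-PB/PC")
CLONAL_KINDS = ("clonal-A", "clonal-B", "clonal-divergent")

#: default synthetic 39-channel panel (names chosen for readability only)
DEFAULT_MARKERS = (
    "CD19", "CD20", "CD22", "CD23", "CD24", "CD27", "CD38", "CD44", "CD45",
    "CD45RA", "CD79B", "CD5", "CD10", "CD11c", "CD138", "HLA-DR", "IgA",
    "IgD", "IgG", "IgM", "Kappa", "Lambda", "CXCR4", "CXCR5", "CD40",
    "CD62L", "CD69", "CD80", "CD83", "CD86", "CD95", "BCL2", "CD25", "CD30",
    "CD31", "CD39", "CD49d", "CD81", "CD98",
)

BASE_LEVEL = 0.2  # arcsinh-scale background mean
HIGH_LEVEL = 2.8  # arcsinh-scale positive mean
LC_POS = 2.5      # light-chain positive mean
LC_NEG = 0.05     # light-chain negative mean
DEFAULT_SD = 0.3


@dataclass(frozen=True)
class PopulationTemplate:
    """One cell population: arcsinh-scale channel means/sds plus identity."""

    name: str
    mean: np.ndarray
    sd: np.ndarray
    light_chain: str
    kind: str

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValidationError(f"template {self.name}: mean/sd shape mismatch")
        if np.any(sd <= 0):
            raise ValidationError(f"template {self.name}: sd must be positive")
        if self.light_chain not in LIGHT_CHAINS:
            raise ValidationError(f"template {self.name}: bad light_chain {self.light_chain!r}")
        if self.kind not in NORMAL_KINDS + CLONAL_KINDS:
            raise ValidationError(f"template {self.name}: bad kind {self.kind!r}")
        if self.is_clonal and self.light_chain == POLYTYPIC:
            raise ValidationError(
                f"template {self.name}: clonal templates must be monotypic"
            )

    @property
    def is_clonal(self) -> bool:
        return self.kind in CLONAL_KINDS


def default_panel(markers: Sequence[str] = DEFAULT_MARKERS) -> MarkerPanel:
    markers = tuple(markers)
    kappa = markers.index("Kappa")
    lam = markers.index("Lambda")
    mask = tuple(i not in (kappa, lam) for i in range(len(markers)))
    return MarkerPanel(markers, kappa, lam, mask)


def make_template(
    panel: MarkerPanel,
    name: str,
    kind: str,
    positive_markers: Sequence[str],
    light_chain: str = POLYTYPIC,
    base: float = BASE_LEVEL,
    high: float = HIGH_LEVEL,
    sd: float = DEFAULT_SD,
) -> PopulationTemplate:
    """Template with ``positive_markers`` at ``high`` and the rest at ``base``."""
    mean = np.full(panel.n_markers, base)
    for m in positive_markers:
        mean[panel.marker_names.index(m)] = high
    return PopulationTemplate(
        name=name,
        mean=mean,
        sd=np.full(panel.n_markers, sd),
        light_chain=light_chain,
        kind=kind,
    )


def default_templates(panel: MarkerPanel, sd: float = DEFAULT_SD) -> dict[str, PopulationTemplate]:
    """Canonical normal B subsets plus clonal templates (synthetic defaults)."""
    mk = lambda *a, **k: make_template(panel, *a, sd=sd, **k)
    return {
        t.name: t
        for t in (
            mk("naive", "normal-naive", ["CD19", "CD20", "CD23", "IgD", "IgM", "CD45"]),
            mk("memory", "normal-memory", ["CD19", "CD20", "CD27", "CD44", "CD45"]),
            mk("gc", "normal-GC", ["CD19", "CD20", "CD10", "CD38", "CD95", "HLA-DR"]),
            mk("pbpc", "normal-PB/PC", ["CD19", "CD38", "CD138", "CD27", "CXCR4"]),
            mk("clone_a", "clonal-A", ["CD19", "CD20", "IgG", "HLA-DR", "CD22", "CD10"],
               light_chain=KAPPA),
            mk("clone_b", "clonal-B", ["CD19", "CD20", "IgM", "CD79B", "CD24", "CD44"],
               light_chain=LAMBDA),
            mk("clone_c", "clonal-divergent", ["CD19", "CD20", "CD11c", "CD30", "CD83"],
               light_chain=KAPPA),
            mk("clone_d", "clonal-divergent", ["CD19", "CD20", "CD5", "CD69", "CD86"],
               light_chain=KAPPA),
            mk("clone_e", "clonal-divergent", ["CD19", "CD20", "CD31", "CD39", "CD25"],
               light_chain=LAMBDA),
        )
    }


@dataclass
class CohortConfig:
    """Everything needed to draw one reproducible cohort."""

    panel: MarkerPanel
    templates: list[PopulationTemplate]
    composition: np.ndarray          # n_samples x n_templates, rows sum to 1
    sample_batch: np.ndarray         # batch index per sample
    batch_factors: np.ndarray        # n_batches x M positive gains
    spillover: SpilloverMatrix
    control_mix: np.ndarray          # template weights of the pooled control
    cells_per_sample: int
    control_cells: int = 400
    sample_names: list[str] | None = None
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.composition.shape[0]

    @property
    def n_batches(self) -> int:
        return self.batch_factors.shape[0]

    def validate(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.ndim != 2 or comp.shape[1] != len(self.templates):
            raise ValidationError("composition must be n_samples x n_templates")
        if np.any(comp < 0):
            raise ValidationError("composition weights must be nonnegative")
        if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("composition rows must sum to 1")
        if self.cells_per_sample <= 0:
            raise ValidationError("cells_per_sample must be positive")
        if self.control_cells <= 0:
            raise ValidationError("control_cells must be positive")
        sb = np.asarray(self.sample_batch)
        if sb.shape != (comp.shape[0],):
            raise ValidationError("sample_batch must have one entry per sample")
        if np.any(sb < 0) or np.any(sb >= self.n_batches):
            raise ValidationError("sample_batch indices out of range")
        bf = np.asarray(self.batch_factors, dtype=float)
        if bf.shape != (self.n_batches, self.panel.n_markers):
            raise ValidationError("batch_factors must be n_batches x n_markers")
        if np.any(bf <= 0):
            raise ValidationError("batch_factors must be positive")
        if self.spillover.n_channels != self.panel.n_markers:
            raise ValidationError("spillover size must match panel")
        cm = np.asarray(self.control_mix, dtype=float)
        if cm.shape != (len(self.templates),) or np.any(cm < 0):
            raise ValidationError("control_mix must be nonnegative per template")
        if not np.isclose(cm.sum(), 1.0, atol=1e-9):
            raise ValidationError("control_mix must sum to 1")
        if self.sample_names is not None and len(self.sample_names) != comp.shape[0]:
            raise ValidationError("sample_names length must equal n_samples")
        # clonal populations within one sample must share one light chain
        for s in range(comp.shape[0]):
            chains = {
                t.light_chain
                for t, w in zip(self.templates, comp[s])
                if w > 0 and t.is_clonal
            }
            if len(chains) > 1:
                raise ValidationError(
                    f"sample {s}: clonal templates mix light chains {sorted(chains)}"
                )


@dataclass
class SyntheticCohort:
    """Simulated raw-scale cells plus ground truth."""

    cells: CellTable
    panel: MarkerPanel
    sample_truth: pd.DataFrame  # sample_id, batch, type, n_subclones, light_chain
    config: CohortConfig


def make_spillover_matrix(M: int, off_diag: float, seed: int = 0) -> SpilloverMatrix:
    """Sparse spillover: identity plus a few directed off-diagonal leaks.

    Each channel spills into its upper neighbor with probability 0.6 and
    magnitude in ``[off_diag/2, off_diag]``; ``off_diag = 0`` yields the
    identity.
    """
    if not (0 <= off_diag < 0.5):
        raise ValidationError("off_diag must be in [0, 0.5)")
    if M < 1:
        raise ValidationError("M must be >= 1")
    rng = np.random.default_rng(seed)
    S = np.eye(M)
    if off_diag > 0:
        for i in range(M - 1):
            if rng.random() < 0.6:
                S[i, i + 1] = off_diag * rng.uniform(0.5, 1.0)
    return SpilloverMatrix(S)


def _intended_type(templates: Sequence[PopulationTemplate], weights: np.ndarray) -> tuple[str, int, str]:
    """Truth tumor type, planted subclone count, and clonal light chain."""
    clonal = [(t, w) for t, w in zip(templates, weights) if w > 0 and t.is_clonal]
    if not clonal:
        return "rLN", 0, POLYTYPIC
    kinds: dict[str, float] = {}
    for t, w in clonal:
        kinds[t.kind] = kinds.get(t.kind, 0.0) + w
    top = max(kinds, key=lambda k: kinds[k])
    label = {"clonal-A": "A", "clonal-B": "B", "clonal-divergent": "NOS"}[top]
    return label, len(clonal), clonal[0][0].light_chain


def _draw_population(
    rng: np.random.Generator,
    template: PopulationTemplate,
    n: int,
    panel: MarkerPanel,
    scale_a: float,
) -> np.ndarray:
    """Raw-scale draws for ``n`` cells of one template (no spillover/batch)."""
    mean = np.tile(template.mean, (n, 1))
    ki, li = panel.kappa_index, panel.lambda_index
    if template.light_chain == POLYTYPIC:
        use_kappa = rng.random(n) < 0.6  # physiologic kappa excess
        mean[:, ki] = np.where(use_kappa, LC_POS, LC_NEG)
        mean[:, li] = np.where(use_kappa, LC_NEG, LC_POS)
    elif template.light_chain == KAPPA:
        mean[:, ki] = LC_POS
        mean[:, li] = LC_NEG
    else:
        mean[:, ki] = LC_NEG
        mean[:, li] = LC_POS
    z = rng.normal(mean, template.sd)
    raw = np.sinh(z) / scale_a
    np.clip(raw, 0.0, None, out=raw)
    return raw


def simulate_cohort(config: CohortConfig, scale_a: float = DEFAULT_SCALE_A) -> SyntheticCohort:
    """Draw the cohort described by ``config`` (bit-reproducible from seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    templates = list(config.templates)
    names = config.sample_names or [f"S{i:03d}" for i in range(config.n_samples)]
    S = config.spillover.matrix
    bf = np.asarray(config.batch_factors, dtype=float)

    tables: list[CellTable] = []
    truth_rows = []

    def finish(raw: np.ndarray, batch: int) -> np.ndarray:
        return (raw @ S) * bf[batch]

    for s in range(config.n_samples):
        weights = np.asarray(config.composition[s], dtype=float)
        counts = rng.multinomial(config.cells_per_sample, weights)
        rows, labels = [], []
        for t, n in zip(templates, counts):
            if n == 0:
                continue
            rows.append(_draw_population(rng, t, n, panel, scale_a))
            labels.extend([t.name] * n)
        raw = np.vstack(rows)
        batch = int(config.sample_batch[s])
        mixed = finish(raw, batch)
        n_cells = mixed.shape[0]
        tables.append(
            CellTable(
                values=mixed,
                marker_names=panel.marker_names,
                sample_id=np.repeat(names[s], n_cells),
                batch_id=np.repeat(f"batch{batch}", n_cells),
                is_control=np.zeros(n_cells, dtype=bool),
                truth=pd.DataFrame({"template": labels}),
            )
        )
        ttype, n_sub, chain = _intended_type(templates, weights)
        truth_rows.append(
            {
                "sample_id": names[s],
                "batch": f"batch{batch}",
                "type": ttype,
                "n_subclones": n_sub,
                "light_chain": chain,
            }
        )

    # one pooled-control aliquot per batch, identical mixture across batches
    for batch in range(config.n_batches):
        counts = rng.multinomial(config.control_cells, config.control_mix)
        rows, labels = [], []
        for t, n in zip(templates, counts):
            if n == 0:
                continue
            rows.append(_draw_population(rng, t, n, panel, scale_a))
            labels.extend([t.name] * n)
        raw = np.vstack(rows)
        mixed = finish(raw, batch)
        n_cells = mixed.shape[0]
        tables.append(
            CellTable(
                values=mixed,
                marker_names=panel.marker_names,
                sample_id=np.repeat(f"control_batch{batch}", n_cells),
                batch_id=np.repeat(f"batch{batch}", n_cells),
                is_control=np.ones(n_cells, dtype=bool),
                truth=pd.DataFrame({"template": labels}),
            )
        )

    cells = concat_tables(tables)
    return SyntheticCohort(
        cells=cells,
        panel=panel,
        sample_truth=pd.DataFrame(truth_rows),
        config=config,
    )


def example_cohort_config(
    n_a: int = 4,
    n_b: int = 4,
    n_divergent: int = 4,
    n_rln: int = 0,
    cells_per_sample: int = 500,
    n_batches: int = 2,
    spillover_off_diag: float = 0.05,
    batch_effect: float | np.ndarray = 0.15,
    secondary_clone_frac: float = 0.25,
    sd: float = DEFAULT_SD,
    control_cells: int = 400,
    seed: int = 0,
) -> CohortConfig:
    """Standard planted cohort used in tests and the demo pipeline.

    Type-A samples carry a dominant GCB-like clone plus a secondary
    divergent clone (planting an A/C co-occurrence and A/B exclusivity);
    type-B samples carry a memory-like clone; divergent samples carry a
    clone matching neither recurrent phenotype; rLN samples contain only
    normal subsets.  ``batch_effect`` is either the log-sd of random
    per-batch gains or an explicit ``n_batches x M`` gain matrix.
    """
    panel = default_panel()
    templates = default_templates(panel, sd=sd)
    order = list(templates)
    idx = {name: i for i, name in enumerate(order)}
    tlist = [templates[n] for n in order]
    M = panel.n_markers

    rows, batches, names = [], [], []
    normals = {"naive": 0.05, "memory": 0.04, "gc": 0.04, "pbpc": 0.02}

    def row(weights: Mapping[str, float]) -> np.ndarray:
        r = np.zeros(len(order))
        for k, v in weights.items():
            r[idx[k]] = v
        return r / r.sum()

    specs: list[tuple[str, Mapping[str, float]]] = []
    clone_share = 1.0 - sum(normals.values())
    for i in range(n_a):
        specs.append(
            (f"A{i}", {**normals,
                       "clone_a": clone_share * (1 - secondary_clone_frac),
                       "clone_c": clone_share * secondary_clone_frac})
        )
    for i in range(n_b):
        specs.append((f"B{i}", {**normals, "clone_b": clone_share}))
    for i in range(n_divergent):
        specs.append((f"D{i}", {**normals, "clone_d": clone_share}))
    for i in range(n_rln):
        specs.append((f"rLN{i}", {"naive": 0.35, "memory": 0.3, "gc": 0.25, "pbpc": 0.1}))

    rng = np.random.default_rng(seed)
    for j, (name, weights) in enumerate(specs):
        names.append(name)
        rows.append(row(weights))
        batches.append(j % n_batches)

    if np.isscalar(batch_effect):
        bf = np.exp(rng.normal(0.0, float(batch_effect), size=(n_batches, M)))
    else:
        bf = np.asarray(batch_effect, dtype=float)

    return CohortConfig(
        panel=panel,
        templates=tlist,
        composition=np.vstack(rows),
        sample_batch=np.array(batches),
        batch_factors=bf,
        spillover=make_spillover_matrix(M, spillover_off_diag, seed=seed + 1),
        control_mix=row({"naive": 0.35, "memory": 0.3, "gc": 0.25, "pbpc": 0.1}),
        cells_per_sample=cells_per_sample,
        control_cells=control_cells,
        sample_names=names,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """One CSV per sample (controls included) plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = cohort.cells
    manifest: dict = {
        "samples": {},
        "markers": list(cells.marker_names),
        "kappa": cohort.panel.kappa_name,
        "lambda": cohort.panel.lambda_name,
        "truth": cohort.sample_truth.to_dict(orient="records"),
    }
    for sid in cells.samples:
        sub = cells.subset(cells.sample_id == sid)
        fname = f"{sid}.csv"
        sub.write_csv(outdir / fname)
        manifest["samples"][str(sid)] = {
            "file": fname,
            "batch": str(sub.batch_id[0]),
            "is_control": bool(sub.is_control[0]),
        }
    cohort.config.spillover.write_csv(outdir / "spillover.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(indir: str | Path) -> tuple[CellTable, MarkerPanel, pd.DataFrame | None]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    tables = [
        CellTable.read_csv(indir / info["file"])
        for info in manifest["samples"].values()
    ]
    cells = concat_tables(tables)
    markers = tuple(manifest["markers"])
    kappa = markers.index(manifest["kappa"])
    lam = markers.index(manifest["lambda"])
    mask = tuple(i not in (kappa, lam) for i in range(len(markers)))
    panel = MarkerPanel(markers, kappa, lam, mask)
    truth = pd.DataFrame(manifest["truth"]) if manifest.get("truth") else None
    return cells, panel, truth
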