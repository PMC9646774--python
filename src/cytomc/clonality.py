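"""Light-chain clonality calls and tumor-type assignment.

Per sample-level cluster, the kappa:lambda balance decides whether the
population is polytypic (ratio within [0.3, 7], bounds inclusive) or
monotypic.  Monotypic clusters that map to otherwise-normal phenotype
groups are flagged with an "Ab" (abnormal) suffix.  Each sample is then
typed from the metacluster composition of its clonal (monotypic) cells:
type A or B when the corresponding recurrent metacluster dominates, NOS
otherwise, and rLN-like when the sample has no monotypic cluster at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellTable, MarkerPanel, ValidationError

POLYTYPIC_LO = 0.3
POLYTYPIC_HI = 7.0
POSITIVITY_THRESHOLD = 1.0  # arcsinh-scale intensity above which a cell is positive

RULE_MOST_ABUNDANT = "most-abundant"
RULE_MAJORITY_50 = "majority-50"

# marker sets that distinguish the two recurrent clone phenotypes
TYPE_A_MARKERS = ("IgG", "HLA-DR", "CD22")
TYPE_B_MARKERS = ("IgM", "CD79B", "CD24", "CD44")


@dataclass
class ClonalityCall:
    sample_id: object
    cluster_id: object
    n_cells: int
    kappa_level: float
    lambda_level: float
    ratio: float
    call: str  # polytypic | monotypic-kappa | monotypic-lambda | indeterminate
    ab_flag: bool = False


def _classify_ratio(ratio: float) -> str:
    if np.isnan(ratio):
        return "indeterminate"
    if ratio > POLYTYPIC_HI:
        return "monotypic-kappa"
    if ratio < POLYTYPIC_LO:
        return "monotypic-lambda"
    return "polytypic"


def call_clonality(
    cells: CellTable,
    labels: np.ndarray,
    panel: MarkerPanel,
    basis: str = "counts",
    positivity_threshold: float = POSITIVITY_THRESHOLD,
    min_cells: int = 0,
) -> list[ClonalityCall]:
    """Clonality call per (sample, cluster).

    ``basis='counts'`` uses the ratio of kappa-positive to lambda-positive
    cell counts at the given arcsinh positivity threshold;
    ``basis='median'`` uses the ratio of median intensities.  A cluster in
    which both signals are zero is reported as ``indeterminate``, as is any
    cluster with fewer than ``min_cells`` cells (too few for a stable
    light-chain ratio).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != cells.n_cells:
        raise ValidationError("labels must align with cells")
    kap = cells.values[:, cells.marker_index(panel.kappa_name)]
    lam = cells.values[:, cells.marker_index(panel.lambda_name)]
    calls: list[ClonalityCall] = []
    for s in pd.unique(cells.sample_id):
        sm = cells.sample_id == s
        for c in np.unique(labels[sm]):
            m = sm & (labels == c)
            if basis == "counts":
                k_level = float((kap[m] > positivity_threshold).sum())
                l_level = float((lam[m] > positivity_threshold).sum())
            elif basis == "median":
                k_level = float(np.median(kap[m]))
                l_level = float(np.median(lam[m]))
            else:
                raise ValidationError(f"unknown basis {basis!r}")
            if k_level == 0 and l_level == 0:
                ratio = float("nan")
            elif l_level == 0:
                ratio = float("inf")
            else:
                ratio = k_level / l_level
            n = int(m.sum())
            call = "indeterminate" if n < min_cells else _classify_ratio(ratio)
            calls.append(
                ClonalityCall(
                    sample_id=s,
                    cluster_id=c,
                    n_cells=n,
                    kappa_level=k_level,
                    lambda_level=l_level,
                    ratio=ratio,
                    call=call,
                )
            )
    return calls


def flag_abnormal(
    calls: list[ClonalityCall],
    normal_phenotype_map: dict,
) -> list[ClonalityCall]:
    """Set ``ab_flag`` on monotypic clusters mapping to normal phenotypes.

    ``normal_phenotype_map`` maps cluster id -> normal phenotype group name,
    or ``None``/absent for tumor-only clusters.  Emits a warning when a
    sample's Ab clusters carry a light chain different from its aberrant
    (tumor-only) monotypic clusters.
    """
    monotypic = {"monotypic-kappa", "monotypic-lambda"}
    per_sample_chain: dict = {}
    for call in calls:
        call.ab_flag = bool(
            call.call in monotypic and normal_phenotype_map.get(call.cluster_id)
        )
        if call.call in monotypic and not call.ab_flag:
            per_sample_chain.setdefault(call.sample_id, set()).add(call.call)
    for call in calls:
        if not call.ab_flag:
            continue
        aberrant = per_sample_chain.get(call.sample_id)
        if aberrant and call.call not in aberrant:
            warnings.warn(
                f"sample {call.sample_id!r}: Ab cluster {call.cluster_id!r} is "
                f"{call.call} but aberrant clusters are {sorted(aberrant)}",
                stacklevel=2,
            )
    return calls


def clonal_cell_mask(
    cells: CellTable, labels: np.ndarray, calls: list[ClonalityCall]
) -> np.ndarray:
    """Boolean mask of cells in monotypic (sample, cluster) populations."""
    labels = np.asarray(labels)
    monotypic = {
        (c.sample_id, c.cluster_id)
        for c in calls
        if c.call in ("monotypic-kappa", "monotypic-lambda")
    }
    out = np.zeros(cells.n_cells, dtype=bool)
    for s, c in monotypic:
        out |= (cells.sample_id == s) & (labels == c)
    return out


@dataclass
class TumorType:
    sample_id: object
    clonal_fraction: float
    mc_composition: pd.Series  # proportions of clonal cells per metacluster
    dominant_mc: object | None
    type: str                  # A | B | NOS | rLN-like
    rule: str


def assign_tumor_type(
    sample_id,
    mc_counts: pd.Series,
    n_b_cells: int,
    mc_a,
    mc_b,
    rule: str = RULE_MOST_ABUNDANT,
) -> TumorType:
    """Type one sample from its clonal-cell metacluster counts.

    ``mc_counts`` are counts of clonal cells per metacluster (empty or
    all-zero means no monotypic population: rLN-like).  ``mc_a`` / ``mc_b``
    name the two recurrent metaclusters.
    """
    if n_b_cells <= 0:
        raise ValidationError(f"sample {sample_id!r} is empty")
    if rule not in (RULE_MOST_ABUNDANT, RULE_MAJORITY_50):
        raise ValidationError(f"unknown typing rule {rule!r}")
    total = float(mc_counts.sum()) if len(mc_counts) else 0.0
    if total == 0:
        return TumorType(
            sample_id=sample_id,
            clonal_fraction=0.0,
            mc_composition=pd.Series(dtype=float),
            dominant_mc=None,
            type="rLN-like",
            rule=rule,
        )
    comp = mc_counts / total
    top = comp.max()
    dominant_set = list(comp[comp == top].index)
    dominant = dominant_set[0] if len(dominant_set) == 1 else None  # tie -> NOS
    if rule == RULE_MOST_ABUNDANT:
        if mc_a is not None and dominant == mc_a:
            ttype = "A"
        elif mc_b is not None and dominant == mc_b:
            ttype = "B"
        else:
            ttype = "NOS"
    else:
        if comp.get(mc_a, 0.0) > 0.5:
            ttype = "A"
        elif comp.get(mc_b, 0.0) > 0.5:
            ttype = "B"
        else:
            ttype = "NOS"
    return TumorType(
        sample_id=sample_id,
        clonal_fraction=total / n_b_cells,
        mc_composition=comp,
        dominant_mc=dominant,
        type=ttype,
        rule=rule,
    )


def designate_ab_metaclusters(
    mc_medians: pd.DataFrame,
    clonal_mc_counts: pd.Series,
    marker_names: tuple[str, ...],
    a_markers=TYPE_A_MARKERS,
    b_markers=TYPE_B_MARKERS,
    contrast_threshold: float = 1.0,
) -> tuple[object, object]:
    """Identify which metaclusters play the MC-A and MC-B roles.

    Among metaclusters containing clonal cells, MC-A is the most abundant
    one whose signature contrast (mean of IgG/HLA-DR/CD22 minus mean of
    IgM/CD79B/CD24/CD44 medians) exceeds ``contrast_threshold``; MC-B the
    most abundant one below ``-contrast_threshold``.  A role with no
    qualifying candidate is ``None`` (no sample can then receive that
    type).  Panels without the signature markers fall back to the two most
    abundant clonal metaclusters.
    """
    counts = clonal_mc_counts[clonal_mc_counts > 0]
    if len(counts) == 0:
        raise ValidationError("no clonal cells to designate metacluster types from")
    by_abundance = list(counts.sort_values(ascending=False).index)
    a_idx = [i for i, m in enumerate(marker_names) if m in a_markers]
    b_idx = [i for i, m in enumerate(marker_names) if m in b_markers]
    if not a_idx or not b_idx:
        if len(by_abundance) == 1:
            return by_abundance[0], None
        return by_abundance[0], by_abundance[1]

    def contrast(mc) -> float:
        prof = mc_medians.loc[mc].to_numpy(dtype=float)
        return float(prof[a_idx].mean() - prof[b_idx].mean())

    mc_a = next((m for m in by_abundance if contrast(m) >= contrast_threshold), None)
    mc_b = next(
        (m for m in by_abundance if m != mc_a and contrast(m) <= -contrast_threshold),
        None,
    )
    return mc_a, mc_b


def typing_table(types: list[TumorType]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in types],
            "type": [t.type for t in types],
            "rule": [t.rule for t in types],
            "clonal_fraction": [t.clonal_fraction for t in types],
            "dominant_mc": [t.dominant_mc for t in types],
            "dominant_share": [
                float(t.mc_composition.max()) if len(t.mc_composition) else 0.0
                for t in types
            ],
        }
    )


def clonality_table(calls: list[ClonalityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "cluster_id": [c.cluster_id for c in calls],
            "n_cells": [c.n_cells for c in calls],
            "kappa_level": [c.kappa_level for c in calls],
            "lambda_level": [c.lambda_level for c in calls],
            "ratio": [c.ratio for c in calls],
            "call": [c.call for c in calls],
            "ab_flag": [c.ab_flag for c in calls],
        }
    )
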