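"""Raw-intensity preprocessing.

Order of operations mirrors standard mass-cytometry practice: spillover
compensation on the raw scale (nonnegative least squares, so no negative
intensities are introduced), control-anchored cross-batch normalization,
then the arcsinh transform ``asinh(a * x)`` with ``a = 0.2`` (cofactor 5).

Batch normalization factors are estimated from the pooled-control aliquot
run in every batch: for each channel, the batch median is divided by the
weakest (smallest) batch median, so factors are >= 1 with the per-channel
minimum anchored at exactly 1.  By default factors are estimated and applied
on the raw scale — median(g*x) = g*median(x), so planted multiplicative
batch effects are recovered exactly; an ``arcsinh`` mode working on
transformed values is available behind the ``scale`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import ARCSINH, KL_CHANNEL, RAW, CellTable, MarkerPanel, ValidationError

DEFAULT_SCALE_A = 0.2  # asinh(a*x): a = 0.2 <-> cofactor 5
MAX_CONDITION = 1e8


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square channel crosstalk matrix.

    ``matrix[i, j]`` is the fraction of channel ``i`` signal observed in
    channel ``j``; the diagonal is 1 and off-diagonal entries lie in [0, 1).
    """

    matrix: np.ndarray
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValidationError("spillover matrix must be square")
        if not np.allclose(np.diag(mat), 1.0):
            raise ValidationError("spillover diagonal must be 1")
        off = mat[~np.eye(mat.shape[0], dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValidationError("off-diagonal spillover must be in [0, 1)")
        if self.channel_names is not None:
            names = tuple(self.channel_names)
            object.__setattr__(self, "channel_names", names)
            if len(names) != mat.shape[0]:
                raise ValidationError("channel_names length must match matrix size")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def write_csv(self, path: str | Path) -> None:
        names = self.channel_names or tuple(f"ch{i}" for i in range(self.n_channels))
        pd.DataFrame(self.matrix, index=list(names), columns=list(names)).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(matrix=df.to_numpy(dtype=float), channel_names=tuple(df.columns))


@dataclass(frozen=True)
class BatchNormFactors:
    """Per-batch, per-channel normalization factors (anchored at min = 1)."""

    factors: pd.DataFrame  # index: batch ids, columns: channel names
    scale: str = RAW  # scale the medians were taken on

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if np.any(f <= 0):
            raise ValidationError("normalization factors must be positive")
        col_min = f.min(axis=0)
        if not np.allclose(col_min, 1.0, atol=1e-9):
            raise ValidationError("per-channel minimum factor must equal 1")

    def for_batch(self, batch) -> np.ndarray:
        if batch not in self.factors.index:
            raise ValidationError(f"unknown batch id {batch!r}")
        return self.factors.loc[batch].to_numpy(dtype=float)

    def write_json(self, path: str | Path) -> None:
        import json

        payload = {
            "scale": self.scale,
            "channels": list(self.factors.columns),
            "factors": {str(b): self.factors.loc[b].tolist() for b in self.factors.index},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def compensate_nnls(cells: CellTable, spillover: SpilloverMatrix) -> CellTable:
    """Invert linear spillover per cell with nonnegative least squares.

    Solves ``argmin_{x >= 0} || S^T x - y ||`` for each observed row ``y``.
    Rows whose unconstrained solution is already nonnegative are handled by
    one vectorized linear solve; only the remainder fall back to per-cell
    NNLS.
    """
    if cells.scale != RAW:
        raise ValidationError("compensation expects raw-scale intensities")
    S = spillover.matrix
    if S.shape[0] != cells.n_markers:
        raise ValidationError(
            f"spillover size {S.shape[0]} does not match {cells.n_markers} markers"
        )
    cond = np.linalg.cond(S)
    if cond > MAX_CONDITION:
        raise ValidationError(f"spillover matrix ill-conditioned (cond={cond:.3g})")
    Y = cells.values
    # unconstrained solution: S^T x = y  =>  X = Y @ inv(S)
    X = np.linalg.solve(S.T, Y.T).T
    bad = np.any(X < 0, axis=1)
    if np.any(bad):
        St = S.T.copy()
        for i in np.flatnonzero(bad):
            X[i], _ = nnls(St, Y[i])
    X[X < 0] = 0.0  # clip numerical negatives from the direct solve
    return cells.with_values(X)


def arcsinh_transform(cells: CellTable, scale_a: float = DEFAULT_SCALE_A) -> CellTable:
    """Elementwise ``asinh(scale_a * x)``."""
    if scale_a <= 0:
        raise ValidationError("scale_a must be positive")
    if cells.scale != RAW:
        raise ValidationError("arcsinh_transform expects raw-scale input")
    return cells.with_values(np.arcsinh(scale_a * cells.values), scale=ARCSINH)


def estimate_batch_factors(controls: CellTable) -> BatchNormFactors:
    """Channel-wise batch factors from pooled-control medians.

    ``f[b, c] = median_c(batch b controls) / min_b' median_c(batch b' controls)``.
    """
    ctrl = controls.subset(controls.is_control) if not controls.is_control.all() else controls
    if ctrl.n_cells == 0:
        raise ValidationError("no control cells provided")
    batches = ctrl.batches
    medians = np.vstack(
        [np.median(ctrl.values[ctrl.batch_id == b], axis=0) for b in batches]
    )
    weakest = medians.min(axis=0)
    zero = np.flatnonzero(weakest == 0)
    if zero.size:
        names = [ctrl.marker_names[i] for i in zero]
        raise ValidationError(f"zero minimum control median in channels {names}")
    factors = medians / weakest
    return BatchNormFactors(
        factors=pd.DataFrame(factors, index=batches, columns=list(ctrl.marker_names)),
        scale=ctrl.scale,
    )


def check_controls_cover_batches(cells: CellTable) -> None:
    with_ctrl = set(cells.batch_id[cells.is_control])
    missing = [b for b in cells.batches if b not in with_ctrl]
    if missing:
        raise ValidationError(f"batches without control aliquot: {missing}")


def apply_batch_normalization(cells: CellTable, factors: BatchNormFactors) -> CellTable:
    """Divide each cell's channels by its batch's factors."""
    if factors.scale != cells.scale:
        raise ValidationError(
            f"factors were estimated on {factors.scale!r} scale but cells are "
            f"{cells.scale!r}"
        )
    fcols = list(factors.factors.columns)
    if fcols != list(cells.marker_names):
        raise ValidationError("factor channels do not match cell table markers")
    out = cells.values.copy()
    for b in cells.batches:
        fb = factors.for_batch(b)
        mask = cells.batch_id == b
        out[mask] = out[mask] / fb
    return cells.with_values(out)


def synthesize_kl(cells: CellTable, panel: MarkerPanel) -> tuple[CellTable, MarkerPanel]:
    """Append the combined light-chain channel KL = max(kappa, lambda).

    The original kappa and lambda channels are retained for clonality
    analysis; the returned panel marks KL as a clustering marker.
    """
    for name in (panel.kappa_name, panel.lambda_name):
        if name not in cells.marker_names:
            raise ValidationError(f"light-chain channel {name!r} missing from table")
    kap = cells.values[:, cells.marker_index(panel.kappa_name)]
    lam = cells.values[:, cells.marker_index(panel.lambda_name)]
    return cells.add_channel(KL_CHANNEL, np.maximum(kap, lam)), panel.with_kl()


def preprocess_pipeline(
    cells: CellTable,
    spillover: SpilloverMatrix | None,
    panel: MarkerPanel,
    scale_a: float = DEFAULT_SCALE_A,
    norm_scale: str = RAW,
) -> tuple[CellTable, MarkerPanel, BatchNormFactors]:
    """Full preprocessing: compensate -> batch-normalize -> arcsinh -> KL.

    With ``norm_scale='arcsinh'`` batch factors are instead estimated and
    applied after the transform.
    """
    if spillover is not None:
        cells = compensate_nnls(cells, spillover)
    check_controls_cover_batches(cells)
    if norm_scale == RAW:
        factors = estimate_batch_factors(cells)
        cells = apply_batch_normalization(cells, factors)
        cells = arcsinh_transform(cells, scale_a)
    elif norm_scale == ARCSINH:
        cells = arcsinh_transform(cells, scale_a)
        factors = estimate_batch_factors(cells)
        cells = apply_batch_normalization(cells, factors)
    else:
        raise ValidationError(f"unknown norm_scale {norm_scale!r}")
    cells, panel_kl = synthesize_kl(cells, panel)
    return cells, panel_kl, factors
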