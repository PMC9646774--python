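"""Core data structures shared across pipeline stages.

The central object is :class:`CellTable`, a cells x markers intensity matrix
with per-cell sample/batch annotations and a scale flag (``raw`` or
``arcsinh``).  :class:`MarkerPanel` records which channels are the two
immunoglobulin light chains and which markers enter clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
ARCSINH = "arcsinh"

#: name of the synthesized combined light-chain channel
KL_CHANNEL = "KL"

META_COLUMNS = ("cell_id", "sample_id", "batch_id", "is_control")


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass(frozen=True)
class MarkerPanel:
    """Marker panel description.

    Parameters
    ----------
    marker_names
        Unique channel identifiers, length M.
    kappa_index, lambda_index
        Positions of the kappa and lambda light-chain channels.
    clustering_mask
        Boolean per marker; ``True`` for markers used in clustering.  The
        light-chain channels themselves must be excluded (a combined ``KL``
        channel, the per-cell max of kappa and lambda, substitutes for them).
    """

    marker_names: tuple[str, ...]
    kappa_index: int
    lambda_index: int
    clustering_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        names = tuple(self.marker_names)
        mask = tuple(bool(m) for m in self.clustering_mask)
        object.__setattr__(self, "marker_names", names)
        object.__setattr__(self, "clustering_mask", mask)
        m = len(names)
        if len(set(names)) != m:
            raise ValidationError("marker_names must be unique")
        if len(mask) != m:
            raise ValidationError("clustering_mask length must equal number of markers")
        for idx, label in ((self.kappa_index, "kappa_index"), (self.lambda_index, "lambda_index")):
            if not (0 <= idx < m):
                raise ValidationError(f"{label} out of range: {idx}")
        if self.kappa_index == self.lambda_index:
            raise ValidationError("kappa_index and lambda_index must differ")
        if mask[self.kappa_index] or mask[self.lambda_index]:
            raise ValidationError(
                "light-chain channels may not carry clustering_mask=True; "
                "the KL channel substitutes for them"
            )
        if sum(mask) < 3:
            raise ValidationError("need at least 3 clustering markers")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def kappa_name(self) -> str:
        return self.marker_names[self.kappa_index]

    @property
    def lambda_name(self) -> str:
        return self.marker_names[self.lambda_index]

    @property
    def clustering_markers(self) -> tuple[str, ...]:
        return tuple(n for n, m in zip(self.marker_names, self.clustering_mask) if m)

    def with_kl(self) -> "MarkerPanel":
        """Panel extended with the combined KL channel (clusterable)."""
        if KL_CHANNEL in self.marker_names:
            return self
        return MarkerPanel(
            marker_names=self.marker_names + (KL_CHANNEL,),
            kappa_index=self.kappa_index,
            lambda_index=self.lambda_index,
            clustering_mask=self.clustering_mask + (True,),
        )


@dataclass
class CellTable:
    """Per-cell marker intensities plus annotations.

    ``values`` is a dense ``(n_cells, n_markers)`` float array.  ``scale``
    flags whether intensities are raw ion counts (nonnegative) or
    arcsinh-transformed.  ``truth`` optionally carries per-cell ground-truth
    columns from the synthetic generator.
    """

    values: np.ndarray
    marker_names: tuple[str, ...]
    sample_id: np.ndarray
    batch_id: np.ndarray
    is_control: np.ndarray
    scale: str = RAW
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.marker_names = tuple(self.marker_names)
        self.sample_id = np.asarray(self.sample_id)
        self.batch_id = np.asarray(self.batch_id)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        n, m = self.values.shape
        if len(self.marker_names) != m:
            raise ValidationError("marker_names length must match value columns")
        for arr, label in (
            (self.sample_id, "sample_id"),
            (self.batch_id, "batch_id"),
            (self.is_control, "is_control"),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{label} must have one entry per cell")
        if self.scale not in (RAW, ARCSINH):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if self.scale == RAW and np.any(self.values < 0):
            raise ValidationError("raw-scale values must be nonnegative")
        # sample -> batch must be single-valued
        mapping: dict = {}
        for s, b in zip(self.sample_id, self.batch_id):
            if mapping.setdefault(s, b) != b:
                raise ValidationError(f"sample {s!r} appears in multiple batches")
        if self.truth is not None and len(self.truth) != n:
            raise ValidationError("truth table length must match number of cells")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list:
        """Unique sample ids in order of first appearance."""
        return list(pd.unique(self.sample_id))

    @property
    def batches(self) -> list:
        return list(pd.unique(self.batch_id))

    def sample_batch_map(self) -> dict:
        return dict(zip(self.sample_id, self.batch_id))

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in table") from None

    def matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Value matrix restricted to ``markers`` (all markers if None)."""
        if markers is None:
            return self.values
        idx = [self.marker_index(m) for m in markers]
        return self.values[:, idx]

    def subset(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return CellTable(
            values=self.values[idx],
            marker_names=self.marker_names,
            sample_id=self.sample_id[idx],
            batch_id=self.batch_id[idx],
            is_control=self.is_control[idx],
            scale=self.scale,
            truth=None if self.truth is None else self.truth.iloc[idx].reset_index(drop=True),
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "CellTable":
        return replace(self, values=values, scale=self.scale if scale is None else scale)

    def add_channel(self, name: str, values: np.ndarray) -> "CellTable":
        if name in self.marker_names:
            raise ValidationError(f"channel {name!r} already present")
        vals = np.column_stack([self.values, np.asarray(values, dtype=float)])
        return replace(self, values=vals, marker_names=self.marker_names + (name,))

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "sample_id": self.sample_id,
                "batch_id": self.batch_id,
                "is_control": self.is_control.astype(int),
            }
        )
        for j, name in enumerate(self.marker_names):
            df[name] = self.values[:, j]
        if self.truth is not None:
            for col in self.truth.columns:
                df[f"truth_{col}"] = self.truth[col].to_numpy()
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = RAW) -> "CellTable":
        truth_cols = [c for c in df.columns if c.startswith("truth_")]
        markers = [c for c in df.columns if c not in META_COLUMNS and c not in truth_cols]
        truth = None
        if truth_cols:
            truth = df[truth_cols].rename(columns=lambda c: c[len("truth_"):])
            truth = truth.reset_index(drop=True)
        return cls(
            values=df[markers].to_numpy(dtype=float),
            marker_names=tuple(markers),
            sample_id=df["sample_id"].to_numpy(),
            batch_id=df["batch_id"].to_numpy(),
            is_control=df["is_control"].to_numpy(dtype=bool),
            scale=scale,
            truth=truth,
        )

    @classmethod
    def read_csv(cls, path: str | Path, scale: str = RAW) -> "CellTable":
        return cls.from_dataframe(pd.read_csv(path), scale=scale)


def concat_tables(tables: Iterable[CellTable]) -> CellTable:
    tables = list(tables)
    if not tables:
        raise ValidationError("cannot concatenate zero tables")
    first = tables[0]
    for t in tables[1:]:
        if t.marker_names != first.marker_names:
            raise ValidationError("marker panels differ between tables")
        if t.scale != first.scale:
            raise ValidationError("scales differ between tables")
    truth = None
    if all(t.truth is not None for t in tables):
        truth = pd.concat([t.truth for t in tables], ignore_index=True)
    return CellTable(
        values=np.vstack([t.values for t in tables]),
        marker_names=first.marker_names,
        sample_id=np.concatenate([t.sample_id for t in tables]),
        batch_id=np.concatenate([t.batch_id for t in tables]),
        is_control=np.concatenate([t.is_control for t in tables]),
        scale=first.scale,
        truth=truth,
    )


def read_fcs(path: str | Path) -> CellTable:  # pragma: no cover - optional dependency
    """Read a single FCS file into a raw-scale CellTable (one sample).

    Requires the optional ``fcsparser`` package; CSV input is the fully
    supported path.
    """
    try:
        import fcsparser
    except ImportError as exc:
        raise ImportError(
            "FCS input requires the optional 'fcsparser' package; "
            "convert to CSV or install fcsparser"
        ) from exc
    meta, data = fcsparser.parse(str(path), reformat_meta=True)
    name = Path(path).stem
    n = len(data)
    return CellTable(
        values=data.to_numpy(dtype=float),
        marker_names=tuple(data.columns),
        sample_id=np.repeat(name, n),
        batch_id=np.repeat("batch0", n),
        is_control=np.zeros(n, dtype=bool),
        scale=RAW,
    )
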