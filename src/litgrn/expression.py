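"""Time-series replicate expression matrices.

An :class:`ExpressionDataset` holds a gene x replicate x timepoint tensor of
expression values together with a presence mask over (replicate, time) arrays:
a microarray experiment may be missing whole arrays, and those are masked out
rather than imputed. Values are min-max normalized to [-1, 1] per gene before
model fitting.

Indices are 0-based throughout the API; column names in the TSV layout are
1-based (``t1_r1`` is the first replicate at the first time point).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .predications import FormatError, ValidationError

_COL_RE = re.compile(r"^t(\d+)_r(\d+)$")


@dataclass
class Transition:
    """One usable time step (t -> t+1) within a replicate, 0-based."""

    replicate: int
    t_from: int

    @property
    def t_to(self) -> int:
        return self.t_from + 1


@dataclass
class ExpressionDataset:
    """Gene x replicate x time expression tensor with a missing-array mask."""

    genes: list[str]
    values: np.ndarray          # shape (n_genes, R, T); NaN where absent
    present: np.ndarray         # shape (R, T) boolean

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n, r, t = self.values.shape
        if len(self.genes) != n:
            raise ValidationError("gene list does not match value tensor")
        if len(set(self.genes)) != n:
            raise ValidationError("duplicate gene symbols")
        if self.present.shape != (r, t):
            raise ValidationError("present mask shape mismatch")
        if n < 1 or r < 1 or t < 1:
            raise ValidationError("need at least one gene/replicate/timepoint")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def n_present_arrays(self) -> int:
        return int(self.present.sum())

    def gene_index(self, symbol: str) -> int:
        return self.genes.index(symbol)

    def write_tsv(self, path: Union[str, Path]) -> None:
        """Write the TSV layout; missing arrays' columns are omitted."""
        data = {"gene": self.genes}
        for t in range(self.n_timepoints):
            for r in range(self.n_replicates):
                if self.present[r, t]:
                    data[f"t{t + 1}_r{r + 1}"] = self.values[:, r, t]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                                  float_format="%.10g")


def read_expression(source: Union[str, Path]) -> ExpressionDataset:
    """Read a gene x (time, replicate) expression TSV.

    The first column is ``gene``; each remaining column is named ``t<k>_r<j>``
    for time point k, replicate j (1-based). Arrays whose column is absent are
    marked missing in the mask.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    if df.columns[0] != "gene":
        raise FormatError("first column must be 'gene'")
    genes = df["gene"].astype(str).tolist()
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(f"duplicate gene rows: {', '.join(dupes)}")
    slots: dict[tuple[int, int], str] = {}
    for col in df.columns[1:]:
        m = _COL_RE.match(col)
        if not m:
            raise FormatError(f"column {col!r} is not of the form t<k>_r<j>")
        t, r = int(m.group(1)), int(m.group(2))
        if t < 1 or r < 1:
            raise FormatError(f"column {col!r}: indices are 1-based")
        slots[(r - 1, t - 1)] = col
    if not slots:
        raise FormatError("no expression columns found")
    R = max(r for r, _ in slots) + 1
    T = max(t for _, t in slots) + 1
    values = np.full((len(genes), R, T), np.nan)
    present = np.zeros((R, T), dtype=bool)
    for (r, t), col in slots.items():
        colvals = pd.to_numeric(df[col], errors="coerce")
        if colvals.isna().any():
            bad = int(colvals.isna().idxmax())
            raise FormatError(
                f"non-numeric value at row {bad + 2}, column {col!r}")
        values[:, r, t] = colvals.to_numpy()
        present[r, t] = True
    return ExpressionDataset(genes=genes, values=values, present=present)


def normalize_expression(ds: ExpressionDataset,
                         per_gene: bool = True) -> ExpressionDataset:
    """Min-max normalize present values onto [-1, 1].

    By default each gene is scaled independently (an affine map of its own
    min/max onto the endpoints); with ``per_gene=False`` one global affine map
    is used. A gene (or dataset) constant across all present arrays maps to 0.
    Idempotent up to floating error; the mask is unchanged.
    """
    vals = ds.values.copy()
    mask = ds.present  # (R, T)
    pres = vals[:, mask]  # (n_genes, n_present)
    if per_gene:
        lo = pres.min(axis=1, keepdims=True)
        hi = pres.max(axis=1, keepdims=True)
    else:
        lo = np.full((ds.n_genes, 1), pres.min())
        hi = np.full((ds.n_genes, 1), pres.max())
    span = hi - lo
    scaled = np.zeros_like(pres)
    nz = (span > 0).ravel()
    scaled[nz] = -1.0 + 2.0 * (pres[nz] - lo[nz]) / span[nz]
    out = np.full_like(vals, np.nan)
    out[:, mask] = scaled
    return ExpressionDataset(genes=list(ds.genes), values=out,
                             present=ds.present.copy())


def usable_transitions(ds: ExpressionDataset) -> list[Transition]:
    """All (replicate, t) steps with both endpoint arrays present."""
    out = []
    for r in range(ds.n_replicates):
        for t in range(ds.n_timepoints - 1):
            if ds.present[r, t] and ds.present[r, t + 1]:
                out.append(Transition(replicate=r, t_from=t))
    return out


def transition_design(ds: ExpressionDataset,
                      transitions: list[Transition] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked one-step design for the linear model.

    Returns ``(X, Y)`` where ``X[m]`` is the full expression vector at the
    source time of transition m (shape ``(m, n_genes)``) and ``Y[m]`` the
    expression vector at the target time (same shape). The fitness of a
    weight vector w for target gene i is ``sum((Y[:, i] - X @ w)**2)``.
    """
    if transitions is None:
        transitions = usable_transitions(ds)
    if not transitions:
        raise ValidationError("no usable transitions in dataset")
    X = np.stack([ds.values[:, tr.replicate, tr.t_from] for tr in transitions])
    Y = np.stack([ds.values[:, tr.replicate, tr.t_to] for tr in transitions])
    return X, Y
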