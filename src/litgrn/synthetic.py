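"""Synthetic ground-truth generators and packaged study fixtures.

Every stage of the pipeline can be exercised without external downloads:

* :func:`generate_network` plants a random signed weight matrix whose rows are
  rescaled to keep the linear dynamics inside [-1, 1];
* :func:`simulate_expression` runs those dynamics forward with Gaussian noise
  and the study's missing-array layout;
* :func:`emit_predications` writes a predication table for the planted edges
  plus controlled spurious content, recording the per-stage survivor counts
  the filtering pipeline must reproduce;
* the ``load_*`` functions expose small packaged tables (per-pathway filtering
  stage counts, the 78-gene p53 pathway list, the manual-validation counts and
  the yeast precision counts) used in tests and worked examples.

Defaults mirror the human breast-cancer study layout: a 78-gene pathway with a
~110-edge literature backbone, 7 time points x 6 replicates with two arrays
missing, and modest Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .ga import Topology
from .predications import (FilterReport, Predication, SymbolMap,
                           ValidationError)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study."""

    n_genes: int = 78
    edge_density: float = 110 / (78 * 78)
    inhibitory_fraction: float = 0.3
    T: int = 7
    R: int = 6
    noise_sd: float = 0.05
    #: (replicate, time) 0-based arrays absent from the experiment; default is
    #: two arrays from different replicates at different time points.
    missing_arrays: list[tuple[int, int]] = field(
        default_factory=lambda: [(1, 3), (4, 5)])
    #: spurious edges emitted per true edge
    spurious_predication_rate: float = 0.1
    distance_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    docfreq_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.2})
    alias_corruption_rate: float = 0.0
    #: fraction of true edges reported as unsigned INTERACTS_WITH
    interacts_fraction: float = 0.0
    #: replicates of one biological time course share the initial state and
    #: diverge only through noise (as replicate arrays of a single experiment
    #: do); set False for fully independent replicate trajectories
    shared_initial_state: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_density", "inhibitory_fraction",
                     "spurious_predication_rate", "alias_corruption_rate",
                     "interacts_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.edge_density == 0:
            pass  # empty topology is legal
        if self.T < 2:
            raise ValidationError("need at least 2 time points")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def generate_network(spec: SyntheticSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[Topology, np.ndarray]:
    """Plant a random signed topology and ground-truth weight matrix.

    Each ordered pair (self-loops included) is an edge independently with
    probability ``edge_density``; true weights have magnitude uniform on
    [0.2, 1] and are negative with probability ``inhibitory_fraction``. Rows
    are rescaled so each row's absolute sum is <= 1, keeping the noise-free
    dynamics inside [-1, 1].
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    allowed = rng.random((n, n)) < spec.edge_density
    mag = rng.uniform(0.2, 1.0, size=(n, n))
    sign = np.where(rng.random((n, n)) < spec.inhibitory_fraction, -1.0, 1.0)
    W = np.where(allowed, mag * sign, 0.0)
    row_sum = np.abs(W).sum(axis=1, keepdims=True)
    scale = np.where(row_sum > 1.0, row_sum, 1.0)
    W = W / scale
    sign_hint = np.sign(W).astype(int)
    topo = Topology(genes=spec.gene_names, allowed=allowed,
                    sign_hint=sign_hint)
    return topo, W


def simulate_expression(truth: np.ndarray, spec: SyntheticSpec,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionDataset, int]:
    """Run the linear dynamics forward per replicate.

    x(1) is uniform on [-1, 1] — shared across replicates by default, per
    replicate if ``shared_initial_state`` is False; x(t+1) = W x(t) + eps with
    eps ~ N(0, noise_sd^2) independently per replicate, clipped to [-1, 1].
    Arrays listed in ``missing_arrays`` are masked out. Returns the dataset
    and the number of clipped values, so noise-free exactness checks can
    require zero clips.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    W = np.asarray(truth, dtype=float)
    n = spec.n_genes
    if W.shape != (n, n):
        raise ValidationError("truth matrix shape mismatch")
    if np.any(np.abs(W).sum(axis=1) > 1 + 1e-9):
        raise ValidationError("truth rows must have absolute sum <= 1")
    values = np.empty((n, spec.R, spec.T))
    n_clipped = 0
    x0_shared = rng.uniform(-1.0, 1.0, size=n)
    for r in range(spec.R):
        x = x0_shared if spec.shared_initial_state else \
            rng.uniform(-1.0, 1.0, size=n)
        values[:, r, 0] = x
        for t in range(1, spec.T):
            x = W @ x
            if spec.noise_sd > 0:
                x = x + rng.normal(0.0, spec.noise_sd, size=n)
            clipped = np.clip(x, -1.0, 1.0)
            n_clipped += int(np.sum(clipped != x))
            x = clipped
            values[:, r, t] = x
    present = np.ones((spec.R, spec.T), dtype=bool)
    for (r, t) in spec.missing_arrays:
        present[r, t] = False
        values[:, r, t] = np.nan
    ds = ExpressionDataset(genes=spec.gene_names, values=values,
                           present=present)
    return ds, n_clipped


def make_alias_map(genes: list[str]) -> SymbolMap:
    """Alias map with one synonym per gene besides the symbol itself."""
    entries = {f"{g.lower()}-syn": g for g in genes}
    entries.update({g: g for g in genes})
    return SymbolMap(entries)


def _draw(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(keys, p=probs))


def emit_predications(topology: Topology, truth: np.ndarray,
                      spec: SyntheticSpec, alias_map: SymbolMap,
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[Predication], FilterReport]:
    """Emit a predication table for the planted network, with known attrition.

    True edges are asserted with distance 1 and a document frequency of at
    least 2; spurious (non-planted) edges are added at
    ``spurious_predication_rate`` per true edge with distances and document
    frequencies drawn from the spec's distributions. A fraction
    ``alias_corruption_rate`` of edges is written with an unmappable subject
    name (all of the edge's rows), so it is pruned at normalization. The
    returned :class:`FilterReport` holds the planted per-stage survivor
    counts for the default pipeline (max_distance 1, min_docs 2).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 1)
    genes = topology.genes
    n = len(genes)
    pmid_counter = 1

    def next_pmids(k: int) -> list[str]:
        nonlocal pmid_counter
        out = [f"PM{pmid_counter + i:07d}" for i in range(k)]
        pmid_counter += k
        return out

    true_edges = [(j, i) for i in range(n) for j in range(n)
                  if topology.allowed[i, j]]   # (source j, target i)
    n_spurious = int(round(spec.spurious_predication_rate * len(true_edges)))
    spurious_edges: list[tuple[int, int]] = []
    true_set = set(true_edges)
    while len(spurious_edges) < n_spurious:
        j, i = int(rng.integers(n)), int(rng.integers(n))
        if (j, i) not in true_set and (j, i) not in spurious_edges:
            spurious_edges.append((j, i))

    rows: list[Predication] = []
    # planted per-stage counts
    n_rows = 0
    n_pass_distance_rows = 0
    n_pass_distance_edges = 0
    n_normalized = 0
    n_frequent = 0

    def emit_edge(j: int, i: int, predicate: str, distance: int,
                  docfreq: int) -> None:
        nonlocal n_rows, n_pass_distance_rows, n_pass_distance_edges, \
            n_normalized, n_frequent
        corrupted = rng.random() < spec.alias_corruption_rate
        subj = f"unmapped-{genes[j].lower()}" if corrupted else \
            (f"{genes[j].lower()}-syn" if rng.random() < 0.5 else genes[j])
        obj = f"{genes[i].lower()}-syn" if rng.random() < 0.5 else genes[i]
        for pmid in next_pmids(docfreq):
            rows.append(Predication(
                pmid=pmid, subject_name=subj, predicate=predicate,
                object_name=obj, subject_distance=1,
                object_distance=distance))
        n_rows += docfreq
        if distance <= 1:
            n_pass_distance_rows += docfreq
            n_pass_distance_edges += 1
            if not corrupted:
                n_normalized += 1
                if docfreq >= 2:
                    n_frequent += 1

    for (j, i) in true_edges:
        if rng.random() < spec.interacts_fraction:
            predicate = "INTERACTS_WITH"
        else:
            predicate = "STIMULATES" if truth[i, j] >= 0 else "INHIBITS"
        docfreq = 2 + _draw({0: 0.6, 1: 0.4}, rng)
        emit_edge(j, i, predicate, distance=1, docfreq=docfreq)
    for (j, i) in spurious_edges:
        predicate = str(rng.choice(["STIMULATES", "INHIBITS",
                                    "INTERACTS_WITH"]))
        emit_edge(j, i, predicate,
                  distance=_draw(spec.distance_distribution, rng),
                  docfreq=_draw(spec.docfreq_distribution, rng))

    report = FilterReport(
        raw=n_rows, after_distance=n_pass_distance_rows,
        after_dedup=n_pass_distance_edges,
        after_normalization=n_normalized, after_frequency=n_frequent)
    return rows, report


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("litgrn.data").joinpath(name)


def load_pathway_stage_counts() -> pd.DataFrame:
    """Per-pathway predication counts at each filtering stage (13 pathways)."""
    with resources.as_file(_data_path("pathway_stage_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_p53_genes() -> list[str]:
    """The 78 official symbols of the KEGG p53 pathway gene set."""
    with resources.as_file(_data_path("p53_pathway_genes.txt")) as p:
        return [line.strip() for line in Path(p).read_text().splitlines()
                if line.strip() and not line.startswith("#")]


def load_validation_counts() -> pd.DataFrame:
    """Manual literature-validation counts for the novel p53 interactions."""
    with resources.as_file(_data_path("p53_validation_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_precision_counts() -> pd.DataFrame:
    """Yeast network precision counts per weight threshold."""
    with resources.as_file(_data_path("yeast_precision_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def jak_stat_probe_path():
    """Path to the packaged 3-predication Jak-STAT filtering probe."""
    return _data_path("jak_stat_probe_predications.tsv")


def write_outputs(outdir: Union[str, Path], spec: SyntheticSpec) -> dict:
    """Generate a full synthetic study and write its artifacts to ``outdir``.

    Writes predications.tsv, symbols.tsv, expression.tsv, truth_edges.tsv and
    truth_counts.tsv; returns a manifest of the written paths.
    """
    from .predications import write_predications

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    topo, W = generate_network(spec, rng)
    ds, n_clipped = simulate_expression(W, spec, rng)
    alias_map = make_alias_map(topo.genes)
    preds, report = emit_predications(topo, W, spec, alias_map, rng)

    paths = {k: outdir / f"{k}.tsv" for k in
             ("predications", "symbols", "expression",
              "truth_edges", "truth_counts")}
    write_predications(preds, paths["predications"])
    alias_map.to_tsv(paths["symbols"])
    ds.write_tsv(paths["expression"])
    edges = [{"source": topo.genes[j], "target": topo.genes[i],
              "weight": W[i, j]}
             for i in range(spec.n_genes) for j in range(spec.n_genes)
             if topo.allowed[i, j]]
    pd.DataFrame(edges, columns=["source", "target", "weight"]).to_csv(
        paths["truth_edges"], sep="\t", index=False)
    report.to_frame().to_csv(paths["truth_counts"], sep="\t", index=False)
    return {"paths": {k: str(v) for k, v in paths.items()},
            "n_clipped": n_clipped}
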