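"""Model assessment: leave-one-out by time point, RMSE, paired t-test.

The protocol holds out all arrays at one time point t*, trains the GA on every
usable transition not touching t*, predicts each gene's expression at t* from
the preceding arrays, and scores the deviation of those predictions from the
replicate-mean observed expression at t*. A random-topology baseline (the
random-gene-selection strategy of earlier models) is evaluated under the same
protocol for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionDataset, usable_transitions
from .ga import GAConfig, Topology, evolve_network
from .predications import ValidationError

logger = logging.getLogger(__name__)


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean square difference between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size == 0 or pred.size != obs.size:
        raise ValidationError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class TTestResult:
    """Paired t-test outcome with degenerate-case flags."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on the differences a - b.

    If the differences have zero spread the statistic is undefined: identical
    vectors report p = 1, a constant nonzero shift reports p = 0; both are
    flagged degenerate.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValidationError("paired t-test needs equal lengths >= 2")
    d = a - b
    m = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=m - 1, p=1.0, degenerate=True)
        return TTestResult(t=np.inf if d.mean() > 0 else -np.inf,
                           df=m - 1, p=0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(m))
    p = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return TTestResult(t=float(t), df=m - 1, p=float(p))


def random_topology(genes: list[str], k: int,
                    rng: np.random.Generator) -> Topology:
    """Each target gene gets k distinct regulators chosen uniformly at random.

    Emulates inference strategies that probe random gene subsets instead of a
    literature-derived backbone. Signs are unhinted.
    """
    n = len(genes)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    allowed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        allowed[i, rng.choice(n, size=k, replace=False)] = True
    return Topology(genes=list(genes), allowed=allowed)


@dataclass
class LOOReport:
    """Leave-one-out-by-timepoint errors for one model."""

    model: str
    held_out_times: list[int]            # 0-based held-out time indices
    fold_rmse: np.ndarray                # (n_folds,)
    gene_rmse: np.ndarray                # (n_folds, n_genes)
    skipped_times: list[int] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.held_out_times)

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse.mean())


def loo_by_timepoint(ds: ExpressionDataset, topology: Topology,
                     config: GAConfig, model: str = "literature",
                     k: int = 10) -> LOOReport:
    """Leave-one-out evaluation over held-out time points.

    Every t* from the second time point onward is a candidate fold (the first
    has no preceding arrays to predict from). Training uses all usable
    transitions with neither endpoint at t*; the fold is scored by pooling,
    over genes and test replicates, the squared deviations of the predicted
    values at t* from the replicate-mean observed value at t*. Folds with no
    test transitions are skipped with a warning.

    ``model`` selects the topology actually trained: ``"literature"`` uses
    ``topology`` as given; ``"random_baseline"`` replaces it with a random
    topology of k regulators per gene (seeded from ``config.rng_seed``).
    """
    if ds.n_timepoints < 3:
        raise ValidationError("leave-one-out needs at least 3 time points")
    if model == "random_baseline":
        rng = np.random.default_rng(config.rng_seed)
        topology = random_topology(topology.genes, k=k, rng=rng)
    elif model != "literature":
        raise ValidationError(f"unknown model {model!r}")

    if topology.genes != ds.genes:
        order = [ds.genes.index(g) for g in topology.genes]
        ds = ExpressionDataset(genes=list(topology.genes),
                               values=ds.values[order],
                               present=ds.present.copy())

    all_transitions = usable_transitions(ds)
    held_out, fold_scores, gene_scores, skipped = [], [], [], []
    for t_star in range(1, ds.n_timepoints):
        test = [tr for tr in all_transitions if tr.t_to == t_star]
        train = [tr for tr in all_transitions
                 if tr.t_from != t_star and tr.t_to != t_star]
        if not test or not train:
            skipped.append(t_star)
            logger.warning("fold t*=%d skipped (no usable transitions)",
                           t_star + 1)
            continue
        W = evolve_network(ds, topology, config, transitions=train)
        # replicate-mean observed expression at the held-out time
        obs_mean = np.nanmean(ds.values[:, ds.present[:, t_star], t_star],
                              axis=1)                       # (n_genes,)
        preds = np.stack([W @ ds.values[:, tr.replicate, tr.t_from]
                          for tr in test])                  # (n_test, n_genes)
        sq = (preds - obs_mean[None, :]) ** 2
        fold_scores.append(float(np.sqrt(sq.mean())))
        gene_scores.append(np.sqrt(sq.mean(axis=0)))
        held_out.append(t_star)
    return LOOReport(model=model, held_out_times=held_out,
                     fold_rmse=np.asarray(fold_scores),
                     gene_rmse=np.stack(gene_scores) if gene_scores
                     else np.empty((0, ds.n_genes)),
                     skipped_times=skipped)


@dataclass
class ModelComparison:
    """Two LOO reports with per-fold and overall paired t-tests."""

    report_a: LOOReport
    report_b: LOOReport
    fold_tests: list[TTestResult]
    overall: TTestResult


def compare_models(report_a: LOOReport, report_b: LOOReport) -> ModelComparison:
    """Paired t-tests between two models evaluated on identical folds.

    Per fold the pairing is over genes; overall it is over every
    (fold, gene) cell.
    """
    if report_a.held_out_times != report_b.held_out_times:
        raise ValidationError("reports cover different folds")
    fold_tests = [paired_ttest(ga, gb) for ga, gb
                  in zip(report_a.gene_rmse, report_b.gene_rmse)]
    overall = paired_ttest(report_a.gene_rmse.ravel(),
                           report_b.gene_rmse.ravel())
    return ModelComparison(report_a=report_a, report_b=report_b,
                           fold_tests=fold_tests, overall=overall)
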