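"""Recursive Feature Addition (RFA).

The chosen gene set grows one gene per step.  At each step every unchosen
gene is scored by the training accuracy of the current set plus that gene;
all genes attaining the maximal count (an exact integer tie) form the
candidate set C, and the tie is resolved by correlation-based redundancy:

* MSC — pick the candidate with the Minimum Sum of squared Pearson
  correlations to the already chosen genes.
* MMC — pick the candidate with the Minimum of the Maximum squared
  correlation to the chosen genes.

Remaining score ties break to the lowest gene index; the very first gene
breaks accuracy ties by the smallest prefilter p-value.  All correlations are
computed on the training samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    AccuracyCount,
    ClassifierSpec,
    candidate_accuracy_counts,
    default_var_floor,
)
from .io_formats import ExpressionDataset


@dataclass
class SelectionTrajectory:
    """Ordered record of one RFA run; the sets G_N are prefixes of ``chosen``."""

    chosen: list            # gene indices g_1..g_D into the dataset rows
    chosen_ids: list        # matching gene identifiers
    train_acc: list         # AccuracyCount per dimension
    criterion: str          # "msc" | "mmc"
    classifier: ClassifierSpec
    mode: str = "loo"

    def __post_init__(self):
        if len(set(self.chosen)) != len(self.chosen):
            raise ValueError("chosen gene indices must be distinct")
        if len(self.train_acc) != len(self.chosen):
            raise ValueError("one accuracy record per chosen gene required")

    def __len__(self):
        return len(self.chosen)

    def prefix(self, dim: int) -> list:
        """The gene indices of G_dim."""
        if not 1 <= dim <= len(self.chosen):
            raise ValueError(f"dimension {dim} outside 1..{len(self.chosen)}")
        return self.chosen[:dim]

    def accuracies(self) -> np.ndarray:
        return np.array([a.accuracy for a in self.train_acc])


@dataclass
class CandidateSet:
    """Genes tied at the maximal training accuracy at one forward step."""

    indices: list
    max_acc: AccuracyCount

    def __post_init__(self):
        if not self.indices:
            raise ValueError("candidate set cannot be empty")


# ---------------------------------------------------------------------------
# Redundancy scores
# ---------------------------------------------------------------------------

def pearson_sq(x, y) -> float:
    """Squared sample Pearson correlation; 0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = (dx * dx).sum()
    vy = (dy * dy).sum()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = (dx * dy).sum() / np.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def _pearson_sq_matrix(cand_rows: np.ndarray, chosen_rows: np.ndarray) -> np.ndarray:
    """cor² between every candidate row and every chosen row, constants → 0."""
    def standardize(a):
        d = a - a.mean(axis=1, keepdims=True)
        norm = np.sqrt((d * d).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(norm > 0, d / norm, 0.0)
        return z

    r = standardize(np.atleast_2d(cand_rows)) @ standardize(np.atleast_2d(chosen_rows)).T
    return np.minimum(r * r, 1.0)


def sc_score(candidate, chosen_vectors) -> float:
    """Sum of squared correlations between a candidate and the chosen genes."""
    if len(chosen_vectors) == 0:
        raise ValueError("chosen set must be non-empty")
    return float(sum(pearson_sq(candidate, g) for g in chosen_vectors))


def mc_score(candidate, chosen_vectors) -> float:
    """Maximum squared correlation between a candidate and the chosen genes."""
    if len(chosen_vectors) == 0:
        raise ValueError("chosen set must be non-empty")
    return float(max(pearson_sq(candidate, g) for g in chosen_vectors))


# ---------------------------------------------------------------------------
# Selection steps
# ---------------------------------------------------------------------------

def _accuracy_counts(ds, prefix, candidates, spec, mode, var_floor):
    X = ds.samples_by_genes()
    return candidate_accuracy_counts(X, ds.labels, prefix, candidates, spec,
                                     mode=mode, var_floor=var_floor)


def select_first_gene(ds: ExpressionDataset, spec: ClassifierSpec,
                      mode: str = "loo",
                      p_values=None,
                      var_floor: float | None = None):
    """Pick g_1: maximal single-gene training accuracy, then lowest p-value,
    then lowest gene index.  Returns ``(gene_index, AccuracyCount)``."""
    if ds.n_genes == 0:
        raise ValueError("dataset has no genes")
    if p_values is None:
        from .preprocessing import welch_p_values
        p_values = welch_p_values(ds)
    p_values = np.asarray(p_values, dtype=float)
    counts = _accuracy_counts(ds, [], list(range(ds.n_genes)), spec, mode, var_floor)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    winner = int(tied[np.lexsort((tied, p_values[tied]))[0]])
    return winner, AccuracyCount(int(best), ds.n_samples)


def select_next_gene(ds: ExpressionDataset, trajectory: SelectionTrajectory,
                     spec: ClassifierSpec,
                     criterion: str | None = None,
                     mode: str | None = None,
                     var_floor: float | None = None):
    """Pick g_{N+1} given the current trajectory.

    Builds the candidate set C of unchosen genes maximising the training
    accuracy of G_N ∪ {g}; if |C| > 1 the MSC (sum) or MMC (max) squared
    correlation to the chosen genes is minimised, final ties to the lowest
    gene index.  Returns ``(gene_index, AccuracyCount, CandidateSet)``.
    """
    criterion = (criterion or trajectory.criterion).lower()
    mode = mode or trajectory.mode
    if criterion not in ("msc", "mmc"):
        raise ValueError(f"criterion must be 'msc' or 'mmc', got {criterion!r}")
    chosen = list(trajectory.chosen)
    unchosen = [g for g in range(ds.n_genes) if g not in set(chosen)]
    if not unchosen:
        raise ValueError("no unchosen genes remain")
    counts = _accuracy_counts(ds, chosen, unchosen, spec, mode, var_floor)
    best = counts.max()
    acc = AccuracyCount(int(best), ds.n_samples)
    cand = CandidateSet(indices=[unchosen[i] for i in np.flatnonzero(counts == best)],
                        max_acc=acc)
    if len(cand.indices) == 1:
        return cand.indices[0], acc, cand
    cor2 = _pearson_sq_matrix(ds.values[cand.indices], ds.values[chosen])
    scores = cor2.sum(axis=1) if criterion == "msc" else cor2.max(axis=1)
    order = np.lexsort((np.asarray(cand.indices), scores))
    return int(cand.indices[order[0]]), acc, cand


def run_rfa(ds: ExpressionDataset, spec: ClassifierSpec,
            criterion: str = "msc",
            max_dim: int = 100,
            mode: str = "loo",
            p_values=None) -> SelectionTrajectory:
    """Run recursive feature addition for ``max_dim`` steps.

    The variance floor for the in-house classifiers is derived once from the
    full training matrix so every candidate is scored under identical
    numerics.  Deterministic for a fixed dataset, spec and criterion.
    """
    if not 1 <= max_dim <= ds.n_genes:
        raise ValueError(f"max_dim must be in 1..{ds.n_genes}, got {max_dim}")
    if criterion.lower() not in ("msc", "mmc"):
        raise ValueError(f"criterion must be 'msc' or 'mmc', got {criterion!r}")
    var_floor = default_var_floor(ds.samples_by_genes())
    g1, acc1 = select_first_gene(ds, spec, mode=mode, p_values=p_values,
                                 var_floor=var_floor)
    traj = SelectionTrajectory(
        chosen=[g1], chosen_ids=[ds.gene_ids[g1]], train_acc=[acc1],
        criterion=criterion.lower(), classifier=spec, mode=mode,
    )
    for _ in range(1, max_dim):
        g, acc, _cand = select_next_gene(ds, traj, spec, var_floor=var_floor)
        traj.chosen.append(g)
        traj.chosen_ids.append(ds.gene_ids[g])
        traj.train_acc.append(acc)
    return traj
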