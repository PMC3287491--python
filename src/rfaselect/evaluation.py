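"""Repeated-split evaluation protocol.

Each experiment run draws a stratified ~1:1 train/test split, prefilters and
normalises using training information only, runs recursive feature addition
on the training half, scores every prefix on the held-out half, and applies
the peephole optimiser to pick a final dimension.  Across I runs and J
dimensions the report carries the training accuracies r(i,j), the testing
accuracies s(i,j), the per-dimension mean testing accuracy s̄(j), and for
each run the mean / maximum testing accuracy over the best-training
dimensions (ms_hr, hs_hr) together with the testing accuracy of the
peephole-chosen dimension (s_lppo).  ms_hr is exactly the expected payoff of
choosing one best-training dimension uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .classifiers import AccuracyCount, ClassifierSpec, default_var_floor, fit_classifier
from .io_formats import ExpressionDataset
from .lppo import run_lppo
from .preprocessing import filter_insignificant, normalize_manorm, welch_p_values
from .rfa_core import run_rfa


@dataclass
class SplitPlan:
    """One stratified train/test partition of the samples."""

    run_index: int
    seed: int
    train_ids: list
    test_ids: list
    train_cols: np.ndarray
    test_cols: np.ndarray


@dataclass
class EvaluationReport:
    runs: int
    max_dim: int
    criterion: str
    classifier: str
    eval_classifier: str
    mode: str
    r_correct: np.ndarray      # (I, J) training correct counts
    r_total: np.ndarray        # (I,) training sample counts
    s_correct: np.ndarray      # (I, J) testing correct counts
    s_total: np.ndarray        # (I,) testing sample counts
    ms_hr: np.ndarray          # (I,)
    hs_hr: np.ndarray          # (I,)
    s_lppo: np.ndarray         # (I,)
    lppo_dim: np.ndarray       # (I,) chosen final dimension per run
    selected_ids: list = field(default_factory=list)  # per run: gene ids in order

    @property
    def r(self) -> np.ndarray:
        return self.r_correct / self.r_total[:, None]

    @property
    def s(self) -> np.ndarray:
        return self.s_correct / self.s_total[:, None]

    @property
    def s_bar(self) -> np.ndarray:
        """Mean testing accuracy per dimension over runs."""
        return self.s.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(run, dimension) table."""
        I, J = self.r_correct.shape
        run, dim = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1), indexing="ij")
        return pd.DataFrame({
            "run": run.ravel(),
            "dim": dim.ravel(),
            "train_acc": self.r.ravel(),
            "test_acc": self.s.ravel(),
        })

    def summary_frame(self) -> pd.DataFrame:
        """Per-run summary: ms_hr, hs_hr, s_lppo, chosen dimension."""
        return pd.DataFrame({
            "run": np.arange(1, self.runs + 1),
            "ms_hr": self.ms_hr,
            "hs_hr": self.hs_hr,
            "s_lppo": self.s_lppo,
            "lppo_dim": self.lppo_dim,
        })


def stratified_split(ds: ExpressionDataset, seed: int, run_index: int = 0) -> SplitPlan:
    """Per class, send a uniformly random ceil(n_c/2) subset to training."""
    rng = np.random.default_rng(seed)
    train_cols = []
    for c in (0, 1):
        cols = np.flatnonzero(ds.labels == c)
        if len(cols) < 2:
            raise ValueError(f"class {ds.class_names[c]!r} has fewer than 2 samples")
        n_train = ceil(len(cols) / 2)
        train_cols.extend(rng.choice(cols, size=n_train, replace=False).tolist())
    train_cols = np.array(sorted(train_cols), dtype=int)
    test_cols = np.setdiff1d(np.arange(ds.n_samples), train_cols)
    return SplitPlan(
        run_index=run_index,
        seed=seed,
        train_ids=[ds.sample_ids[i] for i in train_cols],
        test_ids=[ds.sample_ids[i] for i in test_cols],
        train_cols=train_cols,
        test_cols=test_cols,
    )


def compute_ms_hs(r_row, s_row):
    """Mean and max of the testing accuracies over the best-training dims.

    ``r_row`` may be AccuracyCounts, correct counts, or float accuracies;
    best-training dims are the exact argmax ties of ``r_row``.
    """
    r = np.asarray([x.accuracy if isinstance(x, AccuracyCount) else x for x in r_row],
                   dtype=float)
    s = np.asarray([x.accuracy if isinstance(x, AccuracyCount) else x for x in s_row],
                   dtype=float)
    if r.shape != s.shape or r.ndim != 1 or len(r) == 0:
        raise ValueError("r_row and s_row must be equal-length non-empty vectors")
    best = np.flatnonzero(r == r.max())
    return float(s[best].mean()), float(s[best].max())


def run_experiment(
    ds: ExpressionDataset,
    spec: ClassifierSpec,
    criterion: str = "msc",
    max_dim: int = 100,
    runs: int = 20,
    base_seed: int = 0,
    mode: str = "loo",
    eval_spec: ClassifierSpec | None = None,
    filter_threshold: float = 0.05,
    max_filtered_genes: int | None = None,
    norm: str = "mean",
    l0: int = 2,
    rf_trees: int = 500,
    refilter_per_run: bool = True,
) -> EvaluationReport:
    """Run the full repeated-split protocol.

    Per run i (seeded ``base_seed + i``): stratified split → Welch prefilter
    computed on the training half (or once globally when
    ``refilter_per_run=False``) → per-sample normalisation → RFA on the
    training half → every prefix refit on the training half and scored on the
    test half → peephole optimisation on the training trajectory.  The random
    forest used by the tie-break is seeded from the run seed.
    """
    eval_spec = eval_spec or spec
    if norm not in ("mean", "median", "none"):
        raise ValueError(f"norm must be mean|median|none, got {norm!r}")

    global_keep = None
    if not refilter_per_run:
        _, rep = filter_insignificant(ds, filter_threshold, max_filtered_genes)
        kept = set(rep.kept_gene_ids)
        global_keep = np.array([i for i, g in enumerate(ds.gene_ids) if g in kept])

    I, J = runs, max_dim
    r_correct = np.zeros((I, J), dtype=int)
    s_correct = np.zeros((I, J), dtype=int)
    r_total = np.zeros(I, dtype=int)
    s_total = np.zeros(I, dtype=int)
    ms_hr = np.zeros(I)
    hs_hr = np.zeros(I)
    s_lppo = np.zeros(I)
    lppo_dim = np.zeros(I, dtype=int)
    selected_ids = []

    for i in range(runs):
        seed = base_seed + i
        plan = stratified_split(ds, seed, run_index=i)
        train = ds.subset_samples(plan.train_cols)
        test = ds.subset_samples(plan.test_cols)
        if refilter_per_run:
            p = welch_p_values(train)
            keep = p <= filter_threshold
            if max_filtered_genes and keep.sum() > max_filtered_genes:
                order = np.argsort(p, kind="stable")[:max_filtered_genes]
                keep = np.isin(np.arange(train.n_genes), order) & keep
            keep_idx = np.flatnonzero(keep)
        else:
            keep_idx = global_keep
        if len(keep_idx) < max_dim:
            raise ValueError(
                f"run {i}: only {len(keep_idx)} genes survive the prefilter, "
                f"fewer than max_dim={max_dim}"
            )
        train_f = train.subset_genes(keep_idx)
        test_f = test.subset_genes(keep_idx)
        if norm != "none":  # filter first, then rescale the filtered matrices
            train_f = normalize_manorm(train_f, center=norm)
            test_f = normalize_manorm(test_f, center=norm)

        traj = run_rfa(train_f, spec, criterion=criterion, max_dim=max_dim, mode=mode)

        Xtr = train_f.samples_by_genes()
        Xte = test_f.samples_by_genes()
        floor = default_var_floor(Xtr)
        r_total[i] = train_f.n_samples
        s_total[i] = test_f.n_samples
        for j in range(1, max_dim + 1):
            cols = traj.prefix(j)
            model = fit_classifier(eval_spec, Xtr[:, cols], train_f.labels, floor)
            pred = np.asarray(model.predict(Xte[:, cols]))
            s_correct[i, j - 1] = int((pred == test_f.labels).sum())
            r_correct[i, j - 1] = traj.train_acc[j - 1].correct

        rf_spec = ClassifierSpec(name="rf", hyperparameters={"n_trees": rf_trees},
                                 seed=seed)
        res = run_lppo(train_f, traj, l0=l0, rf_spec=rf_spec)
        lppo_dim[i] = res.final_dim
        s_lppo[i] = s_correct[i, res.final_dim - 1] / s_total[i]
        ms_hr[i], hs_hr[i] = compute_ms_hs(
            [AccuracyCount(c, r_total[i]) for c in r_correct[i]],
            [AccuracyCount(c, s_total[i]) for c in s_correct[i]],
        )
        selected_ids.append(list(traj.chosen_ids))

    return EvaluationReport(
        runs=runs, max_dim=max_dim, criterion=criterion, classifier=spec.name,
        eval_classifier=eval_spec.name, mode=mode,
        r_correct=r_correct, r_total=r_total,
        s_correct=s_correct, s_total=s_total,
        ms_hr=ms_hr, hs_hr=hs_hr, s_lppo=s_lppo, lppo_dim=lppo_dim,
        selected_ids=selected_ids,
    )
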