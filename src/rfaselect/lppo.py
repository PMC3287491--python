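"""Lagging Prediction Peephole Optimization (LPPO).

Forward selection typically reaches its peak *training* accuracy early and
holds it over a plateau, while the model that generalises best tends to lag
behind the first attainment.  LPPO picks the final dimension from that
plateau: collect every dimension with the maximal training accuracy (HR),
discard the initial best run, score a symmetric window ("peephole") of
2l+1 dimensions around each survivor by its mean training accuracy, break
window ties by the mean out-of-bag error of a seeded random forest fit on
each prefix in the window, and widen l until a unique window remains.  The
centre of the winning window is the final feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .classifiers import ClassifierSpec, rf_oob_error
from .io_formats import ExpressionDataset
from .rfa_core import SelectionTrajectory


@dataclass
class PeepholeWindow:
    """A candidate centre dimension with its half-width and window means."""

    center: int
    half_width: int
    dims: list                      # dimensions within [center-l, center+l] ∩ [1, D]
    mp_r: float                     # mean training accuracy over dims
    mp_oob_e: float | None = None   # mean OOB error over dims, once requested
    mp_r_exact: Fraction | None = None  # exact value used for tie detection

    def __post_init__(self):
        if self.center not in self.dims:
            raise ValueError("window centre must lie inside the window")


@dataclass
class LppoResult:
    final_dim: int
    final_gene_ids: list
    hr_dims: list
    excluded_dims: list
    windows_examined: list
    expansions: int
    fallback: bool = False          # True when HRC would have been empty
    safeguard: bool = False         # True when the smallest-centre exit fired


def build_hr(trajectory: SelectionTrajectory) -> list:
    """Dimensions whose training accuracy equals the trajectory maximum."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    best = max(trajectory.train_acc)
    return [j for j, a in enumerate(trajectory.train_acc, start=1) if a == best]


def exclude_initial_best(hr) -> tuple:
    """Drop the maximal contiguous run of dimensions starting at min(HR).

    Returns ``(hrc, fallback)``; when removing the initial run would empty the
    set (the plateau never recurs), the full HR is returned with
    ``fallback=True`` so a final set can still be chosen.
    """
    hr = sorted(hr)
    if not hr:
        raise ValueError("HR must be non-empty")
    run_end = 0
    while run_end + 1 < len(hr) and hr[run_end + 1] == hr[run_end] + 1:
        run_end += 1
    hrc = hr[run_end + 1:]
    if not hrc:
        return list(hr), True
    return hrc, False


def score_window(trajectory: SelectionTrajectory, center: int,
                 half_width: int) -> PeepholeWindow:
    """Mean training accuracy over the 2l+1 window, truncated to [1, D].

    Boundary windows average over the dimensions actually present rather than
    padding; the exact rational mean is retained for tie detection.
    """
    D = len(trajectory)
    if not 1 <= center <= D:
        raise ValueError(f"centre {center} outside 1..{D}")
    if half_width < 0:
        raise ValueError("half-width must be >= 0")
    dims = list(range(max(1, center - half_width), min(D, center + half_width) + 1))
    fracs = [trajectory.train_acc[j - 1].as_fraction() for j in dims]
    exact = sum(fracs, Fraction(0)) / len(fracs)
    return PeepholeWindow(center=center, half_width=half_width, dims=dims,
                          mp_r=float(exact), mp_r_exact=exact)


def oob_tiebreak(ds: ExpressionDataset, trajectory: SelectionTrajectory,
                 windows, rf_spec: ClassifierSpec,
                 _cache: dict | None = None) -> list:
    """Populate each window's mean OOB error and return the minimisers.

    For every prefix dimension m covered by any window, a random forest is fit
    on the training samples restricted to G_m and its OOB error recorded; the
    fits are cached across windows (and expansion rounds) sharing prefixes.
    """
    if rf_spec.name != "rf":
        raise ValueError("oob_tiebreak needs an rf ClassifierSpec")
    cache = _cache if _cache is not None else {}
    X = ds.samples_by_genes()
    for w in windows:
        errs = []
        for m in w.dims:
            if m not in cache:
                cache[m] = rf_oob_error(X[:, trajectory.prefix(m)], ds.labels, rf_spec)
            errs.append(cache[m])
        w.mp_oob_e = float(np.mean(errs))
    best = min(round(w.mp_oob_e, 12) for w in windows)
    return [w for w in windows if round(w.mp_oob_e, 12) == best]


def run_lppo(ds: ExpressionDataset | None, trajectory: SelectionTrajectory,
             l0: int = 2,
             rf_spec: ClassifierSpec | None = None) -> LppoResult:
    """Choose the final dimension of a trajectory by peephole optimisation.

    ``ds`` must be the training dataset the trajectory was selected on; it is
    only touched when the OOB tie-break fires, so it may be None for
    trajectories whose window means already decide.  If window ties persist
    once the half-width reaches the trajectory length, the smallest centre
    wins (parsimony safeguard).
    """
    D = len(trajectory)
    if D == 0:
        raise ValueError("empty trajectory")
    hr = build_hr(trajectory)
    hrc, fallback = exclude_initial_best(hr)
    examined = []
    oob_cache: dict = {}
    l = max(0, int(l0))
    expansions = 0
    safeguard = False
    while True:
        windows = [score_window(trajectory, k, l) for k in hrc]
        examined.extend(windows)
        best = max(w.mp_r_exact for w in windows)
        tied = [w for w in windows if w.mp_r_exact == best]
        if len(tied) > 1 and rf_spec is not None:
            tied = oob_tiebreak(ds, trajectory, tied, rf_spec, _cache=oob_cache)
        if len(tied) == 1:
            final = tied[0]
            break
        if l >= D:
            safeguard = True
            final = min(tied, key=lambda w: w.center)
            break
        l += 1
        expansions += 1
    k = final.center
    return LppoResult(
        final_dim=k,
        final_gene_ids=list(trajectory.chosen_ids[:k]),
        hr_dims=hr,
        excluded_dims=[d for d in hr if d not in hrc] if not fallback else [],
        windows_examined=examined,
        expansions=expansions,
        fallback=fallback,
        safeguard=safeguard,
    )
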