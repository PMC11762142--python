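"""Ranking evaluation: AUC against ground truth and scenario grids.

The AUC of a gene ranking equals the Mann-Whitney statistic — here the
fraction of (DEG, non-DEG) pairs in which the DEG receives the smaller
score (ties count one half). Exact pair counting via the rank-sum formula
is used rather than trapezoidal ROC integration: the two are identical by
theorem, and the rank-sum form handles ties exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .calling import run_mbcdeg
from .counts_io import design_from_labels
from .simulate import SimulationScenario, simulate_counts

__all__ = ["EvaluationRecord", "auc", "run_grid", "records_to_frame"]


@dataclass(frozen=True)
class EvaluationRecord:
    p_deg: float
    p_a: float
    fc: float
    G: int
    n_a: int
    n_b: int
    variant: int
    trial: int
    seed: int
    auc: float

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def auc(scores, truth) -> float:
    """AUC of a ranking where *lower* score means *more* differentially expressed.

    ``truth`` is a per-gene is-DEG indicator. Computed as the fraction of
    (DEG, non-DEG) pairs with score_DEG < score_nonDEG, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one DEG and one non-DEG")
    ranks = stats.rankdata(scores)
    u1 = ranks[truth].sum() - n1 * (n1 + 1) / 2.0
    return float((n1 * n0 - u1) / (n1 * n0))


def run_grid(
    p_degs,
    p_as,
    fc: float,
    G: int,
    n_a: int,
    n_b: int,
    variants,
    trials: int,
    base_seed: int,
    K: int = 3,
) -> list:
    """Evaluate MBCdeg variants over a (p_deg, p_a) scenario grid.

    For each condition and trial one dataset is simulated
    (seed = base_seed + trial) and shared across all variants, so methods
    are compared on identical data. Records are sorted by
    (p_deg, p_a, variant, trial).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    records = []
    for p_deg in p_degs:
        for p_a in p_as:
            for trial in range(trials):
                seed = int(base_seed) + trial
                scenario = SimulationScenario(
                    G=G, n_a=n_a, n_b=n_b, p_deg=p_deg, p_a=p_a,
                    fc_a=fc, fc_b=fc, seed=seed,
                )
                ds = simulate_counts(scenario)
                design = design_from_labels(["A"] * n_a + ["B"] * n_b)
                for variant in variants:
                    result, _ = run_mbcdeg(ds.counts, design, variant, K=K, seed=seed)
                    records.append(
                        EvaluationRecord(
                            p_deg=float(p_deg), p_a=float(p_a), fc=float(fc),
                            G=G, n_a=n_a, n_b=n_b, variant=int(variant),
                            trial=trial, seed=seed,
                            auc=auc(result.scores, ds.is_deg),
                        )
                    )
    records.sort(key=lambda r: (r.p_deg, r.p_a, r.variant, r.trial))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate evaluation records (one row per record)."""
    return pd.DataFrame([asdict(r) for r in records])
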