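"""Synthetic two-group RNA-seq count data with known DEG structure.

A fraction ``p_deg`` of genes is differentially expressed; of those, a
fraction ``p_a`` is up-regulated ``fc_a``-fold in group A ("DEG1") and the
rest up-regulated ``fc_b``-fold in group B ("DEG2"). Baseline expression
levels are log-normal and counts are negative binomial around
depth * baseline * fold-change. Truth-class counts are exact (rounded
products, not binomial draws) and occupy fixed leading positions — the
clustering is order-blind, and fixed positions make fixtures trivial.

The fold change is applied one-sidedly (the up-regulated group's mean is
multiplied; the other group stays at baseline); under the zero-sum effect
parameterization this corresponds to ideal cluster centers
(ln sqrt(FC), -ln sqrt(FC)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .counts_io import CountMatrix

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "assign_truth",
    "simulate_counts",
    "fig2_scenario",
]

DEFAULT_BASELINE_MEANLOG = math.log(100.0)
DEFAULT_BASELINE_SDLOG = 1.2
DEFAULT_DISPERSION = 0.28


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated two-group comparison.

    ``p_deg`` is the DEG proportion, ``p_a`` the fraction of DEGs up in
    group A, ``fc_a``/``fc_b`` the fold changes of the two DEG patterns.
    ``depth_factors`` are relative sequencing depths (all 1 by default).
    """

    G: int
    n_a: int
    n_b: int
    p_deg: float
    p_a: float
    fc_a: float = 4.0
    fc_b: float = 4.0
    baseline_meanlog: float = DEFAULT_BASELINE_MEANLOG
    baseline_sdlog: float = DEFAULT_BASELINE_SDLOG
    dispersion: float = DEFAULT_DISPERSION
    depth_factors: tuple = field(default=())
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_deg <= 1.0 and 0.0 <= self.p_a <= 1.0):
            raise ValueError("p_deg and p_a must lie in [0, 1]")
        if self.G < 1 or self.n_a < 1 or self.n_b < 1:
            raise ValueError("G, n_a and n_b must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        depth = self.depth_factors
        if not depth:
            depth = tuple(1.0 for _ in range(self.n_a + self.n_b))
        depth = tuple(float(d) for d in depth)
        if len(depth) != self.n_a + self.n_b:
            raise ValueError("depth_factors must have one entry per sample")
        if any(d <= 0 for d in depth):
            raise ValueError("depth_factors must be positive")
        object.__setattr__(self, "depth_factors", depth)

    @property
    def n_samples(self) -> int:
        return self.n_a + self.n_b

    def truth_counts(self) -> tuple:
        """Exact (n_deg1, n_deg2, n_nondeg) gene counts."""
        n_deg = round(self.G * self.p_deg)
        n_deg1 = round(self.G * self.p_deg * self.p_a)
        return (n_deg1, n_deg - n_deg1, self.G - n_deg)


@dataclass(frozen=True)
class SimulatedDataset:
    counts: CountMatrix
    truth: tuple            # per-gene label in {"non-DEG", "DEG1", "DEG2"}
    scenario: SimulationScenario

    @property
    def is_deg(self) -> np.ndarray:
        return np.array([t != "non-DEG" for t in self.truth])


def assign_truth(G: int, p_deg: float, p_a: float) -> tuple:
    """Deterministic truth layout: DEG1 genes first, then DEG2, then non-DEG."""
    n_deg = round(G * p_deg)
    n_deg1 = round(G * p_deg * p_a)
    n_deg2 = n_deg - n_deg1
    return ("DEG1",) * n_deg1 + ("DEG2",) * n_deg2 + ("non-DEG",) * (G - n_deg)


def simulate_counts(scenario: SimulationScenario) -> SimulatedDataset:
    """Draw one dataset from a scenario; bitwise-deterministic given its seed."""
    rng = np.random.default_rng(scenario.seed)
    truth = assign_truth(scenario.G, scenario.p_deg, scenario.p_a)
    lam = rng.lognormal(scenario.baseline_meanlog, scenario.baseline_sdlog, scenario.G)
    fc = np.ones((scenario.G, scenario.n_samples))
    truth_arr = np.array(truth)
    in_a = np.arange(scenario.n_samples) < scenario.n_a
    fc[np.ix_(truth_arr == "DEG1", in_a)] = scenario.fc_a
    fc[np.ix_(truth_arr == "DEG2", ~in_a)] = scenario.fc_b
    depth = np.asarray(scenario.depth_factors)
    mean = depth[None, :] * lam[:, None] * fc
    if scenario.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / scenario.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    gene_ids = tuple(f"gene_{i + 1}" for i in range(scenario.G))
    sample_ids = tuple(
        [f"A{i + 1}" for i in range(scenario.n_a)] + [f"B{i + 1}" for i in range(scenario.n_b)]
    )
    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64))
    return SimulatedDataset(counts=cm, truth=truth, scenario=scenario)


def fig2_scenario(seed: int = 0) -> SimulationScenario:
    """The canonical worked-example scenario: 2000 genes, 5 vs 6 samples,
    20% DEGs of which 90% are 4-fold up in group A and 10% are 9-fold up
    in group B."""
    return SimulationScenario(
        G=2000, n_a=5, n_b=6, p_deg=0.2, p_a=0.9, fc_a=4.0, fc_b=9.0, seed=seed
    )
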