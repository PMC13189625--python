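"""Seeded simulation of bait-vs-control spectral-count tables.

The generator plants a known fraction of "true interactor" proteins whose
expected count is elevated ``fold_true``-fold in the bait condition, on top
of a contaminant background whose expected count is identical in bait and
control. Counts are drawn from a Gamma-Poisson (negative binomial) law with
variance ``mu + dispersion * mu**2``; at ``dispersion = 0`` this is exactly
Poisson, which matches the count model the interaction scorer assumes.
True interactors can additionally drop out of individual control samples
with probability ``dropout_ctrl`` (bait-only hits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import BAIT, CONTROL, SpectralCountTable


@dataclass
class CountSimConfig:
    """Study conditions for one simulated pull-down experiment.

    Defaults mirror a two-repeat design (two bait and two control samples,
    i.e. the whole experiment performed twice) over a proteome-scale
    background with a small planted interactome.
    """

    n_proteins: int = 2000
    frac_true: float = 0.05
    n_bait_reps: int = 2
    n_ctrl_reps: int = 2
    background_mean: float = 5.0
    fold_true: float = 6.0
    dispersion: float = 0.0
    dropout_ctrl: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_bait_reps <= 0 or self.n_ctrl_reps <= 0:
            raise ValueError("replicate counts must be positive")
        if not 0.0 <= self.frac_true <= 1.0:
            raise ValueError("frac_true must lie in [0, 1]")
        if self.fold_true <= 1.0:
            raise ValueError("fold_true must exceed 1")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.dropout_ctrl <= 1.0:
            raise ValueError("dropout_ctrl must lie in [0, 1]")


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with E[X]=mean, Var[X]=mean+dispersion*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_count_table(config: CountSimConfig) -> tuple[SpectralCountTable, pd.Series]:
    """Simulate a count table and return it with per-protein truth labels.

    Returns
    -------
    table
        :class:`SpectralCountTable` with columns ``bait_1..n`` then
        ``ctrl_1..n``.
    truth
        Boolean Series indexed by protein_id; True marks a planted
        interactor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    protein_ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")

    n_true = int(round(config.frac_true * n))
    truth = np.zeros(n, dtype=bool)
    truth[:n_true] = True

    bait_mean = np.where(truth, config.background_mean * config.fold_true,
                         config.background_mean)
    ctrl_mean = np.full(n, config.background_mean)

    cols: dict[str, np.ndarray] = {}
    for r in range(config.n_bait_reps):
        cols[f"bait_{r + 1}"] = nb_counts(rng, bait_mean, config.dispersion)
    for r in range(config.n_ctrl_reps):
        x = nb_counts(rng, ctrl_mean, config.dispersion)
        if config.dropout_ctrl > 0 and n_true:
            drop = rng.random(n) < config.dropout_ctrl
            x = np.where(truth & drop, 0, x)
        cols[f"ctrl_{r + 1}"] = x

    counts = pd.DataFrame(cols, index=protein_ids)
    conditions = {c: (BAIT if c.startswith("bait") else CONTROL) for c in counts.columns}
    table = SpectralCountTable(counts=counts, conditions=conditions)
    return table, pd.Series(truth, index=protein_ids, name="is_interactor")
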