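"""Fold enrichment, SAINT-style interaction probabilities, candidate calling,
and cross-species conservation of candidate interactomes.

The scoring model
-----------------
For each protein the bait/control contrast is summarised two ways:

* a pseudocounted mean ratio ``(mean_bait + c) / (mean_ctrl + c)``, with a
  strict species-dependent threshold (e.g. >3-fold for mouse, >2-fold for
  zebrafish), and
* a SAINT-style posterior probability of true interaction. Per protein,
  the false-interaction rate is ``lam_F = mean control count + c`` and the
  true-interaction rate ``lam_T = max(mean bait count, m * lam_F)`` with
  ``m`` a floor keeping the true component above the false one. Each bait
  replicate count ``x_i`` gets the two-component posterior

      p_i = pi * f(x_i | lam_T) / [pi * f(x_i | lam_T) + (1 - pi) * f(x_i | lam_F)]

  with ``f`` a Poisson (optionally negative-binomial) pmf and ``pi`` the
  prior probability of a true interaction. The score is the mean of the
  ``p_i`` over bait replicates, so it lives in [0, 1] and equals ``pi``
  exactly when the two components coincide.

A protein is a candidate interactor when it passes both filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .counts import SpectralCountTable


@dataclass
class ScoringConfig:
    """Thresholds and model parameters for candidate calling.

    ``ratio_threshold`` defaults to 3.0 (mouse convention); use 2.0 for the
    zebrafish arm. ``dispersion`` switches the count likelihood from Poisson
    (0.0) to negative binomial.
    """

    ratio_threshold: float = 3.0
    saint_threshold: float = 0.5
    pseudocount: float = 0.5
    prior_true: float = 0.1
    min_fold_constraint: float = 1.0
    dispersion: float = 0.0

    def validate(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if not 0.0 <= self.saint_threshold <= 1.0:
            raise ValueError("saint_threshold must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0.0 < self.prior_true < 1.0:
            raise ValueError("prior_true must lie in (0, 1)")
        if self.min_fold_constraint < 1.0:
            raise ValueError("min_fold_constraint must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


SPECIES_RATIO_THRESHOLDS = {"zebrafish": 2.0, "mouse": 3.0}


def config_for_species(species: str, **overrides) -> ScoringConfig:
    """ScoringConfig with the species' default ratio threshold applied."""
    if species not in SPECIES_RATIO_THRESHOLDS:
        raise ValueError(
            f"unknown species {species!r}; expected one of "
            f"{sorted(SPECIES_RATIO_THRESHOLDS)}"
        )
    overrides.setdefault("ratio_threshold", SPECIES_RATIO_THRESHOLDS[species])
    return ScoringConfig(**overrides)


def _count_pmf(x: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return stats.poisson.pmf(x, mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return stats.nbinom.pmf(x, r, p)


def posterior_probability(x, lam_true, lam_false, prior: float,
                          dispersion: float = 0.0) -> np.ndarray:
    """Two-component posterior that a count ``x`` came from the
    true-interaction rate ``lam_true`` rather than ``lam_false``.

    This is the per-replicate quantity averaged into the interaction score;
    it is non-decreasing in ``x`` whenever ``lam_true >= lam_false``.
    """
    num = prior * _count_pmf(np.asarray(x), np.asarray(lam_true), dispersion)
    den = num + (1.0 - prior) * _count_pmf(np.asarray(x), np.asarray(lam_false),
                                           dispersion)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), prior)


def score_table(table: SpectralCountTable, config: ScoringConfig | None = None) -> pd.DataFrame:
    """Compute enrichment ratios, SAINT-style scores and candidate flags.

    Returns a DataFrame indexed by protein_id with columns ``mean_bait``,
    ``mean_ctrl``, ``ratio``, ``saint_score``, ``passes_ratio``,
    ``passes_saint``, ``candidate``.
    """
    config = config or ScoringConfig()
    config.validate()
    bait = table.bait_matrix().astype(float)
    ctrl = table.control_matrix().astype(float)

    mean_bait = bait.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    c = config.pseudocount
    ratio = (mean_bait + c) / (mean_ctrl + c)

    lam_f = mean_ctrl + c
    lam_t = np.maximum(mean_bait, config.min_fold_constraint * lam_f)
    saint = posterior_probability(bait, lam_t[:, None], lam_f[:, None],
                                  config.prior_true, config.dispersion).mean(axis=1)

    passes_ratio = ratio > config.ratio_threshold
    passes_saint = saint > config.saint_threshold
    return pd.DataFrame(
        {
            "mean_bait": mean_bait,
            "mean_ctrl": mean_ctrl,
            "ratio": ratio,
            "saint_score": saint,
            "passes_ratio": passes_ratio,
            "passes_saint": passes_saint,
            "candidate": passes_ratio & passes_saint,
        },
        index=table.protein_ids,
    )


def compute_fold_enrichment(table: SpectralCountTable,
                            config: ScoringConfig | None = None) -> pd.DataFrame:
    """Per-protein pseudocounted mean ratios and the strict ratio filter."""
    return score_table(table, config)[["mean_bait", "mean_ctrl", "ratio", "passes_ratio"]]


def saint_score(table: SpectralCountTable,
                config: ScoringConfig | None = None) -> pd.DataFrame:
    """Per-protein SAINT-style posterior scores and the score filter."""
    return score_table(table, config)[["saint_score", "passes_saint"]]


def select_candidates(records: pd.DataFrame,
                      config: ScoringConfig | None = None) -> pd.DataFrame:
    """Filter scored records to candidates, sorted for deterministic output.

    Candidates pass both the ratio and the score filter; the list is sorted
    by descending ratio with protein_id as tie-break.
    """
    required = {"ratio", "passes_ratio", "passes_saint"}
    if not required <= set(records.columns):
        raise ValueError(f"records must contain columns {sorted(required)}")
    cand = records[records["passes_ratio"] & records["passes_saint"]].copy()
    cand["candidate"] = True
    return (
        cand.assign(_pid=cand.index.astype(str))
        .sort_values(["ratio", "_pid"], ascending=[False, True], kind="mergesort")
        .drop(columns="_pid")
    )


@dataclass
class OrthologyMap:
    """Many-to-many cross-species protein correspondence."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        clean = []
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("orthology ids must be non-empty")
            if a == b:
                raise ValueError(f"self-pair not allowed: {a!r}")
            clean.append((str(a), str(b)))
        self.pairs = clean

    def a_to_b(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def b_to_a(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ConservationSummary:
    """Cross-species overlap of two candidate lists under an orthology map."""

    n_candidates_a: int
    n_candidates_b: int
    n_shared: int
    jaccard: float
    shared_ids: list[str] = field(default_factory=list)
    empty_map_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "n_candidates_a": self.n_candidates_a,
            "n_candidates_b": self.n_candidates_b,
            "n_shared": self.n_shared,
            "jaccard": self.jaccard,
            "shared_ids": self.shared_ids,
            "empty_map_warning": self.empty_map_warning,
        }


def crossspecies_overlap(candidates_a: list[str] | pd.Index,
                         candidates_b: list[str] | pd.Index,
                         orthology: OrthologyMap) -> ConservationSummary:
    """Overlap of two species' candidate lists through an orthology map.

    A protein in list A is *shared* when any of its orthologues appears in
    list B. The Jaccard index is ``n_shared / (n_A + n_B - n_shared)``
    computed over the two lists.
    """
    set_a = list(dict.fromkeys(str(x) for x in candidates_a))
    set_b = set(str(x) for x in candidates_b)
    if len(orthology) == 0:
        return ConservationSummary(
            n_candidates_a=len(set_a), n_candidates_b=len(set_b),
            n_shared=0, jaccard=0.0, shared_ids=[], empty_map_warning=True,
        )
    fwd = orthology.a_to_b()
    shared = [a for a in set_a if fwd.get(a, set()) & set_b]
    n_a, n_b, n_s = len(set_a), len(set_b), len(shared)
    denom = n_a + n_b - n_s
    return ConservationSummary(
        n_candidates_a=n_a, n_candidates_b=n_b, n_shared=n_s,
        jaccard=(n_s / denom) if denom else 0.0,
        shared_ids=sorted(shared),
    )


def export_edge_table(candidates: list[str] | pd.Index,
                      edges: pd.DataFrame) -> pd.DataFrame:
    """Subset an edge list to edges between candidate proteins.

    ``edges`` must have columns ``source``, ``target`` and optionally
    ``weight``; the induced-subgraph edge set over the candidate ids is
    returned with a ``weight`` column (1.0 where absent).
    """
    need = {"source", "target"}
    if not need <= set(edges.columns):
        raise ValueError("edge table needs 'source' and 'target' columns")
    cand = set(str(x) for x in candidates)
    out = edges[edges["source"].astype(str).isin(cand)
                & edges["target"].astype(str).isin(cand)].copy()
    if "weight" not in out.columns:
        out["weight"] = 1.0
    return out[["source", "target", "weight"]].reset_index(drop=True)
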