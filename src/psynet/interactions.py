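"""Seeded dyadic and triadic interaction screening with the Stay/Swap rule.

Seeds are characteristics whose baseline probability of higher
prevalence clears 90% toward one outcome. Each seed is paired with
every other catalog characteristic (or every unordered pair of them,
for triads); the tuple is treated as a single co-occurrence entity and
given the same Beta-posterior comparison as the baseline. Tuples
occurring five or fewer times across both groups are discarded
(rarity). A surviving tuple is a "Stay" when its probability clears the
threshold toward the seed's own direction, a "Swap" when it clears it
toward the opposite direction, and otherwise discarded as
indeterminate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .baseline import (
    BaselineResult,
    DEFAULT_PRIOR,
    EpiStats,
    beta_posterior,
    clears_threshold,
    epi_stats,
    prob_greater,
)
from .cohort import Cohort, CohortValidationError, Outcome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Seed:
    characteristic: str
    direction: str  # "IMPV" or "MC"
    baseline_prob: float  # p_higher_impv of the characteristic


@dataclass(frozen=True)
class InteractionResult:
    members: tuple[str, ...]  # first member is the seed
    k_impv: int
    k_mc: int
    n_impv: int
    n_mc: int
    p_higher_impv: Optional[float]  # None when discarded for rarity
    designation: str  # "Stay", "Swap" or "Discarded"
    discard_reason: Optional[str]  # "rarity" or "indeterminate"
    epi: Optional[EpiStats]
    duplicate_of: Optional[tuple[str, ...]] = None  # same member set, earlier seed

    @property
    def total_occurrences(self) -> int:
        return self.k_impv + self.k_mc


def select_seeds(baseline: Sequence[BaselineResult], min_prob: float = 0.9) -> list[Seed]:
    """Characteristics whose baseline probability clears ``min_prob``.

    Probabilities are oriented toward IMPV, so values <= 1 - min_prob
    indicate the MC direction by conservation of probability.
    """
    seeds = []
    for r in baseline:
        direction = clears_threshold(r.p_higher_impv, min_prob)
        if direction is not None:
            seeds.append(Seed(r.characteristic, direction, r.p_higher_impv))
    return seeds


def tuple_prevalence(cohort: Cohort, members: Sequence[str]) -> dict[str, tuple[int, int]]:
    """Per-group (k, n): children expressing ALL members, over group size."""
    if cohort.outcome_labels is None:
        raise CohortValidationError("tuple prevalence requires a labeled cohort")
    unknown = set(members) - set(cohort.catalog.ids)
    if unknown:
        raise CohortValidationError(f"unknown characteristic ids: {sorted(unknown)}")
    mem = set(members)
    counts = {"IMPV": [0, 0], "MC": [0, 0]}
    for r in cohort.records:
        g = cohort.outcome_labels[r.child_id].value
        counts[g][1] += 1
        if mem <= r.characteristics:
            counts[g][0] += 1
    return {g: (k, n) for g, (k, n) in counts.items()}


def classify_interaction(
    seed: Seed,
    members: Sequence[str],
    tuple_counts: dict[str, tuple[int, int]],
    prior: tuple[float, float] = DEFAULT_PRIOR,
    min_prob: float = 0.9,
    min_occurrences: int = 6,
) -> InteractionResult:
    """Stay/Swap/Discard designation for one tuple entity.

    Tuples with fewer than ``min_occurrences`` total occurrences (i.e.
    five or less under the default) are discarded before any posterior
    is computed.
    """
    k_i, n_i = tuple_counts["IMPV"]
    k_m, n_m = tuple_counts["MC"]
    base = dict(members=tuple(members), k_impv=k_i, k_mc=k_m, n_impv=n_i, n_mc=n_m)
    if k_i + k_m < min_occurrences:
        return InteractionResult(
            **base, p_higher_impv=None, designation="Discarded",
            discard_reason="rarity", epi=None,
        )
    p = prob_greater(beta_posterior(k_i, n_i, prior), beta_posterior(k_m, n_m, prior))
    from .baseline import ContingencyTable

    epi = epi_stats(ContingencyTable(k_i, k_m, n_i - k_i, n_m - k_m))
    tuple_dir = clears_threshold(p, min_prob)
    if tuple_dir is None:
        return InteractionResult(
            **base, p_higher_impv=p, designation="Discarded",
            discard_reason="indeterminate", epi=epi,
        )
    designation = "Stay" if tuple_dir == seed.direction else "Swap"
    return InteractionResult(
        **base, p_higher_impv=p, designation=designation, discard_reason=None, epi=epi,
    )


def _expression_matrix(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Boolean expression matrix plus an IMPV mask, for fast tuple counts."""
    ids = cohort.catalog.ids
    idx = {cid: k for k, cid in enumerate(ids)}
    X = np.zeros((len(cohort.records), len(ids)), dtype=bool)
    impv = np.zeros(len(cohort.records), dtype=bool)
    for r_i, r in enumerate(cohort.records):
        for cid in r.characteristics:
            X[r_i, idx[cid]] = True
        impv[r_i] = cohort.outcome_labels[r.child_id] is Outcome.IMPV
    return X, impv, idx


def _scan(
    cohort: Cohort,
    baseline: Sequence[BaselineResult],
    order: int,
    prior: tuple[float, float],
    min_prob: float,
    min_occurrences: int,
) -> list[InteractionResult]:
    if cohort.outcome_labels is None:
        raise CohortValidationError("interaction scan requires a labeled cohort")
    seeds = select_seeds(baseline, min_prob)
    if not seeds:
        logger.warning("no seed characteristics at min_prob=%.2f; empty scan", min_prob)
        return []
    X, impv, idx = _expression_matrix(cohort)
    n_i = int(impv.sum())
    n_m = int((~impv).sum())
    results: list[InteractionResult] = []
    seen: dict[frozenset, tuple[str, ...]] = {}
    for seed in seeds:
        others = [c for c in cohort.catalog.ids if c != seed.characteristic]
        partner_sets = (
            [(p,) for p in others] if order == 2 else list(itertools.combinations(others, 2))
        )
        s_col = X[:, idx[seed.characteristic]]
        for partners in partner_sets:
            members = (seed.characteristic, *partners)
            mask = s_col.copy()
            for p in partners:
                mask &= X[:, idx[p]]
            counts = {
                "IMPV": (int((mask & impv).sum()), n_i),
                "MC": (int((mask & ~impv).sum()), n_m),
            }
            res = classify_interaction(seed, members, counts, prior, min_prob, min_occurrences)
            key = frozenset(members)
            if key in seen:
                res = InteractionResult(
                    **{f: getattr(res, f) for f in (
                        "members", "k_impv", "k_mc", "n_impv", "n_mc",
                        "p_higher_impv", "designation", "discard_reason", "epi")},
                    duplicate_of=seen[key],
                )
            else:
                seen[key] = members
            results.append(res)
    return results


def dyad_scan(
    cohort: Cohort,
    baseline: Sequence[BaselineResult],
    prior: tuple[float, float] = DEFAULT_PRIOR,
    min_prob: float = 0.9,
    min_occurrences: int = 6,
) -> list[InteractionResult]:
    """Every (seed, partner) pair over the catalog."""
    return _scan(cohort, baseline, 2, prior, min_prob, min_occurrences)


def triad_scan(
    cohort: Cohort,
    baseline: Sequence[BaselineResult],
    prior: tuple[float, float] = DEFAULT_PRIOR,
    min_prob: float = 0.9,
    min_occurrences: int = 6,
) -> list[InteractionResult]:
    """Every (seed, partner, partner) triple, mirroring the dyad rules."""
    return _scan(cohort, baseline, 3, prior, min_prob, min_occurrences)


def interactions_to_frame(results: Iterable[InteractionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "members": "|".join(r.members),
                "seed": r.members[0],
                "k_impv": r.k_impv,
                "k_mc": r.k_mc,
                "n_impv": r.n_impv,
                "n_mc": r.n_mc,
                "total_occurrences": r.total_occurrences,
                "p_higher_impv": r.p_higher_impv,
                "designation": r.designation,
                "discard_reason": r.discard_reason,
                "odds_ratio": r.epi.odds_ratio if r.epi else None,
                "arr": r.epi.arr if r.epi else None,
                "par_pct": r.epi.par_pct if r.epi else None,
                "duplicate_of": "|".join(r.duplicate_of) if r.duplicate_of else None,
            }
        )
    return pd.DataFrame(rows)


def interaction_graph(results: Iterable[InteractionResult]) -> nx.Graph:
    """Seed-partner graph of surviving dyads (stay/swap edge attribute)."""
    G = nx.Graph()
    for r in results:
        if r.designation in ("Stay", "Swap") and len(r.members) == 2:
            G.add_edge(*r.members, relation=r.designation.lower(),
                       p_higher_impv=float(r.p_higher_impv))
    return G


def write_interactions(
    results: Sequence[InteractionResult], csv_path: str | Path,
    graphml_path: str | Path | None = None, tsv_path: str | Path | None = None,
) -> None:
    interactions_to_frame(results).to_csv(csv_path, index=False)
    if graphml_path or tsv_path:
        G = interaction_graph(results)
        if graphml_path:
            nx.write_graphml(G, graphml_path)
        if tsv_path:
            rows = [
                {"seed": u, "partner": v, **data} for u, v, data in G.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
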