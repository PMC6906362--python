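"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: two
outcome groups of configurable size, sparse binary characteristic
vectors with group-specific marginal prevalences, latent-class
co-occurrence structure (cliques), planted pairwise interactions whose
joint prevalence can oppose the members' marginal direction (the
"swap" phenomenon), and lab trajectories correlated with the BMI/A
z-score change through a generating improvement threshold.

Every draw flows from a single :class:`numpy.random.Generator` seeded
from the scenario, so generation is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import (
    CatalogEntry,
    CharacteristicCatalog,
    Cohort,
    CohortRecord,
    CohortValidationError,
    LabPanelPair,
    LabValues,
    Outcome,
    Sex,
)


class InfeasibleJointPrevalenceError(CohortValidationError):
    """A planted pair's joint prevalence violates the Frechet bounds."""


@dataclass(frozen=True)
class PlantedDyad:
    """A characteristic pair with a specified joint prevalence per group.

    ``expected`` records the designation the construction aims at
    ("Stay" or "Swap") for use as ground truth in recovery checks.
    """

    pair: tuple[str, str]
    joint_prevalence: tuple[float, float]  # (q_impv, q_mc)
    expected: Optional[str] = None


@dataclass(frozen=True)
class LatentClass:
    """A within-group subpopulation overriding selected prevalences."""

    weight: float
    overrides: dict[str, float]


@dataclass(frozen=True)
class LabModel:
    """Generative model linking lab improvement to BMI/A z-score change.

    ``dz_mean``/``dz_sd`` give the per-group distribution of
    delta-z = z_entry - z_exit (positive = improvement). Children whose
    delta-z clears ``dz_threshold`` improve all three biomarkers with
    probability ``improvement_rate_above``, otherwise
    ``improvement_rate_below``. Baseline lab values are log-normal
    around typical elevated levels for an obese pediatric cohort.
    """

    dz_threshold: float = 0.747
    dz_mean: dict[str, float] = field(default_factory=lambda: {"IMPV": 1.1, "MC": 0.2})
    dz_sd: dict[str, float] = field(default_factory=lambda: {"IMPV": 0.25, "MC": 0.25})
    improvement_rate_above: float = 0.85
    improvement_rate_below: float = 0.07
    baseline_medians: dict[str, float] = field(
        default_factory=lambda: {"insulin": 20.0, "triglycerides": 130.0, "homa_ir": 3.5}
    )
    noise_scale: float = 0.3  # log-scale sd of baseline lab values

    def validate(self) -> None:
        for r in (self.improvement_rate_above, self.improvement_rate_below):
            if not 0 <= r <= 1:
                raise CohortValidationError(f"improvement rate {r} outside [0,1]")
        for g, sd in self.dz_sd.items():
            if sd <= 0:
                raise CohortValidationError(f"dz_sd[{g}] must be > 0")
        if self.noise_scale <= 0:
            raise CohortValidationError("noise_scale must be > 0")


@dataclass(frozen=True)
class SimulationScenario:
    catalog: CharacteristicCatalog
    marginal_prevalence: dict[str, tuple[float, float]]  # id -> (p_impv, p_mc)
    n_impv: int = 128
    n_mc: int = 372
    planted_dyads: tuple[PlantedDyad, ...] = ()
    latent_classes: dict[str, tuple[LatentClass, ...]] = field(
        default_factory=lambda: {"IMPV": (), "MC": ()}
    )
    lab_model: LabModel = field(default_factory=LabModel)
    sex_male_share: dict[str, float] = field(
        default_factory=lambda: {"IMPV": 0.64, "MC": 0.47}
    )
    age_mean: dict[str, float] = field(default_factory=lambda: {"IMPV": 6.07, "MC": 7.04})
    age_sd: dict[str, float] = field(default_factory=lambda: {"IMPV": 2.24, "MC": 2.24})
    z_entry_mean: float = 2.8
    z_entry_sd: float = 0.7
    n_lab_subset: int = 150
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_impv + self.n_mc < 2:
            raise CohortValidationError("need at least 2 children in total")
        ids = set(self.catalog.ids)
        for cid, (pi, pm) in self.marginal_prevalence.items():
            if cid not in ids:
                raise CohortValidationError(f"prevalence given for unknown id {cid!r}")
            for p in (pi, pm):
                if not 0 <= p <= 1:
                    raise CohortValidationError(f"prevalence {p} for {cid!r} outside [0,1]")
        for cid in ids:
            if cid not in self.marginal_prevalence:
                raise CohortValidationError(f"no marginal prevalence for {cid!r}")
        planted_members: set[str] = set()
        for dyad in self.planted_dyads:
            i, j = dyad.pair
            if i == j:
                raise CohortValidationError(f"planted dyad with identical members {i!r}")
            if planted_members & {i, j}:
                raise CohortValidationError(
                    f"characteristic in more than one planted dyad: {dyad.pair}"
                )
            planted_members |= {i, j}
            for g, q in zip(("IMPV", "MC"), dyad.joint_prevalence):
                gi = 0 if g == "IMPV" else 1
                pi, pj = self.marginal_prevalence[i][gi], self.marginal_prevalence[j][gi]
                lo, hi = max(0.0, pi + pj - 1.0), min(pi, pj)
                if not lo - 1e-12 <= q <= hi + 1e-12:
                    raise InfeasibleJointPrevalenceError(
                        f"pair {dyad.pair} in {g}: joint {q} outside Frechet bounds "
                        f"[{lo:.4f}, {hi:.4f}] for marginals ({pi}, {pj})"
                    )
        for g, classes in self.latent_classes.items():
            if classes:
                w = sum(c.weight for c in classes)
                if abs(w - 1.0) > 1e-9:
                    raise CohortValidationError(f"latent class weights for {g} sum to {w}, not 1")
                for c in classes:
                    overlap = set(c.overrides) & planted_members
                    if overlap:
                        raise CohortValidationError(
                            f"latent-class override on planted-dyad member(s) {sorted(overlap)}"
                        )
                    for cid, p in c.overrides.items():
                        if cid not in ids:
                            raise CohortValidationError(f"override for unknown id {cid!r}")
                        if not 0 <= p <= 1:
                            raise CohortValidationError(f"override {p} outside [0,1]")
        for g, s in self.sex_male_share.items():
            if not 0 <= s <= 1:
                raise CohortValidationError(f"sex_male_share[{g}]={s} outside [0,1]")
        self.lab_model.validate()

    def effective_prevalence(self, cid: str, group: str) -> float:
        """Mixture-weighted marginal prevalence of ``cid`` in ``group``."""
        gi = 0 if group == "IMPV" else 1
        base = self.marginal_prevalence[cid][gi]
        classes = self.latent_classes.get(group, ())
        if not classes:
            return base
        return sum(c.weight * c.overrides.get(cid, base) for c in classes)


@dataclass(frozen=True)
class GroundTruth:
    """Realized generation facts, recounted directly from the cohort."""

    target_prevalence: dict[str, dict[str, float]]  # group -> id -> mixture target
    realized_prevalence: dict[str, dict[str, float]]  # group -> id -> empirical
    planted_dyads: tuple[PlantedDyad, ...]
    realized_joint_counts: dict[str, dict[str, int]]  # "i|j" -> group -> count
    dz_threshold: float
    latent_class_assignment: dict[str, int]  # child_id -> class index within its group
    labs_improved: dict[str, bool]  # child_id -> all-three-improved (lab subset only)
    group_sizes: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_dyads"] = [dataclasses.asdict(p) for p in self.planted_dyads]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def _draw_pair_cells(
    rng: np.random.Generator, n: int, pi: float, pj: float, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated Bernoulli pairs from the 2x2 cell distribution."""
    probs = np.array([q, pi - q, pj - q, 1.0 - pi - pj + q])
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    cells = rng.choice(4, size=n, p=probs)
    xi = (cells == 0) | (cells == 1)
    xj = (cells == 0) | (cells == 2)
    return xi, xj


def generate_cohort(scenario: SimulationScenario) -> tuple[Cohort, GroundTruth]:
    """Generate a labeled cohort and its ground truth.

    Characteristics are drawn per latent class, then planted pairs are
    overwritten by a joint 2x2 cell draw that matches the stated
    marginals and joint exactly in expectation. Ground-truth recounts
    are verified against the emitted cohort before returning.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.rng_seed)
    groups = {"IMPV": scenario.n_impv, "MC": scenario.n_mc}
    ids = scenario.catalog.ids
    planted_members = {m for d in scenario.planted_dyads for m in d.pair}

    records: list[CohortRecord] = []
    labels: dict[str, Outcome] = {}
    class_assignment: dict[str, int] = {}
    labs_improved: dict[str, bool] = {}
    group_of: dict[str, str] = {}
    dz_of: dict[str, float] = {}

    for group, n in groups.items():
        gi = 0 if group == "IMPV" else 1
        classes = scenario.latent_classes.get(group, ())
        if classes:
            weights = np.array([c.weight for c in classes])
            cls = rng.choice(len(classes), size=n, p=weights / weights.sum())
        else:
            cls = np.zeros(n, dtype=int)

        # per-record prevalence matrix (n x n_chars)
        X = np.zeros((n, len(ids)), dtype=bool)
        for k, cid in enumerate(ids):
            base = scenario.marginal_prevalence[cid][gi]
            if classes and cid not in planted_members:
                p_vec = np.array([classes[c].overrides.get(cid, base) for c in cls])
            else:
                p_vec = np.full(n, base)
            X[:, k] = rng.random(n) < p_vec

        # impose planted joints (overwrites the independent draws)
        idx = {cid: k for k, cid in enumerate(ids)}
        for dyad in scenario.planted_dyads:
            i, j = dyad.pair
            pi = scenario.marginal_prevalence[i][gi]
            pj = scenario.marginal_prevalence[j][gi]
            q = dyad.joint_prevalence[gi]
            xi, xj = _draw_pair_cells(rng, n, pi, pj, q)
            X[:, idx[i]] = xi
            X[:, idx[j]] = xj

        sexes = rng.random(n) < scenario.sex_male_share[group]
        ages = np.clip(
            rng.normal(scenario.age_mean[group], scenario.age_sd[group], n), 0.0, 12.0
        )
        dz = rng.normal(scenario.lab_model.dz_mean[group], scenario.lab_model.dz_sd[group], n)
        z_entry = rng.normal(scenario.z_entry_mean, scenario.z_entry_sd, n)

        for r in range(n):
            cid = f"{group.lower()}_{r:04d}"
            chars = frozenset(ids[k] for k in np.flatnonzero(X[r]))
            records.append(
                CohortRecord(
                    child_id=cid,
                    sex=Sex.MALE if sexes[r] else Sex.FEMALE,
                    age_years=float(ages[r]),
                    characteristics=chars,
                    z_bmi_entry=float(z_entry[r]),
                    z_bmi_exit=float(z_entry[r] - dz[r]),
                    labs=None,
                )
            )
            labels[cid] = Outcome(group)
            class_assignment[cid] = int(cls[r])
            group_of[cid] = group
            dz_of[cid] = float(dz[r])

    # lab subset: labs correlated with delta-z through the generating threshold
    lm = scenario.lab_model
    n_total = len(records)
    n_lab = min(scenario.n_lab_subset, n_total)
    lab_idx = rng.choice(n_total, size=n_lab, replace=False) if n_lab else np.array([], int)
    analytes = ("insulin", "triglycerides", "homa_ir")
    for ri in sorted(lab_idx):
        rec = records[ri]
        dz = dz_of[rec.child_id]
        rate = lm.improvement_rate_above if dz >= lm.dz_threshold else lm.improvement_rate_below
        improved = bool(rng.random() < rate)
        first = {a: float(lm.baseline_medians[a] * np.exp(rng.normal(0, lm.noise_scale)))
                 for a in analytes}
        if improved:
            factors = {a: float(rng.uniform(0.60, 0.95)) for a in analytes}
        else:
            factors = {a: float(rng.uniform(0.70, 1.30)) for a in analytes}
            # force at least one analyte to not improve (flat or worse)
            stuck = analytes[int(rng.integers(len(analytes)))]
            factors[stuck] = float(rng.uniform(1.00, 1.40))
        last = {a: first[a] * factors[a] for a in analytes}
        records[ri] = dataclasses.replace(
            rec,
            labs=LabPanelPair(first=LabValues(**first), last=LabValues(**last)),
        )
        labs_improved[rec.child_id] = improved

    cohort = Cohort(scenario.catalog, tuple(records), labels)

    # ground truth with direct recount verification
    target = {
        g: {cid: scenario.effective_prevalence(cid, g) for cid in ids} for g in groups
    }
    # planted members use their stated marginals regardless of classes
    for g in groups:
        gi = 0 if g == "IMPV" else 1
        for m in planted_members:
            target[g][m] = scenario.marginal_prevalence[m][gi]

    realized = {g: {} for g in groups}
    joint_counts: dict[str, dict[str, int]] = {}
    by_group = {g: [r for r in records if group_of[r.child_id] == g] for g in groups}
    for g, recs in by_group.items():
        n = len(recs)
        for cid in ids:
            realized[g][cid] = sum(cid in r.characteristics for r in recs) / n if n else 0.0
    for dyad in scenario.planted_dyads:
        i, j = dyad.pair
        key = f"{i}|{j}"
        joint_counts[key] = {
            g: sum(i in r.characteristics and j in r.characteristics for r in recs)
            for g, recs in by_group.items()
        }

    gt = GroundTruth(
        target_prevalence=target,
        realized_prevalence=realized,
        planted_dyads=scenario.planted_dyads,
        realized_joint_counts=joint_counts,
        dz_threshold=lm.dz_threshold,
        latent_class_assignment=class_assignment,
        labs_improved=labs_improved,
        group_sizes={g: len(recs) for g, recs in by_group.items()},
    )
    _verify_recount(cohort, gt)
    return cohort, gt


def _verify_recount(cohort: Cohort, gt: GroundTruth) -> None:
    """Assert ground-truth recounts match the emitted cohort exactly."""
    by_group: dict[str, list[CohortRecord]] = {"IMPV": [], "MC": []}
    for r in cohort.records:
        by_group[cohort.outcome_labels[r.child_id].value].append(r)
    for g, recs in by_group.items():
        assert gt.group_sizes[g] == len(recs)
        n = len(recs)
        for cid in cohort.catalog.ids:
            emp = sum(cid in r.characteristics for r in recs) / n if n else 0.0
            assert abs(gt.realized_prevalence[g][cid] - emp) < 1e-12


# ---------------------------------------------------------------------------
# Default scenario: the study conditions
# ---------------------------------------------------------------------------

#: Cycle of sparse background prevalences, typical of first-assessment
#: psychological trait records.
_BACKGROUND_CYCLE = (0.02, 0.03, 0.05, 0.08)

STRONG_IMPV = ("c01", "c02", "g01")  # (0.40, 0.10) planted baseline signals
STRONG_MC = ("c03", "g02", "g03")  # (0.10, 0.40)
NULL_CHARACTERISTICS = ("c04", "g04")  # equal prevalence 0.25
STAY_DYAD = PlantedDyad(("c01", "g06"), (0.30, 0.03), expected="Stay")
SWAP_DYAD = PlantedDyad(("c02", "g07"), (0.01, 0.10), expected="Swap")

#: Characteristics carrying the latent-class co-occurrence structure.
#: Their mixture-weighted marginal is balanced across groups so classes
#: shape *within-group* co-occurrence, not baseline signals.
COMMUNITY_IDS = tuple(f"c{i:02d}" for i in range(6, 13)) + tuple(
    f"g{i:02d}" for i in range(8, 15)
)
_COMMUNITY_BASE = 0.05
_COMMUNITY_EFFECTIVE = 0.175  # target marginal in both groups


def _boost_for(weight: float, base: float = _COMMUNITY_BASE,
               target: float = _COMMUNITY_EFFECTIVE) -> float:
    """Within-class prevalence giving the target mixture marginal."""
    return (target - (1.0 - weight) * base) / weight


def default_catalog() -> CharacteristicCatalog:
    entries = [CatalogEntry(f"c{i:02d}", f"child characteristic {i}", "child") for i in range(1, 29)]
    entries += [
        CatalogEntry(f"g{i:02d}", f"guardian characteristic {i}", "guardian")
        for i in range(1, 50)
    ]
    return CharacteristicCatalog(tuple(entries))


def default_scenario(rng_seed: int = 0) -> SimulationScenario:
    """The study-mirroring scenario: 128/372 children, 28+49 characteristics.

    Includes strong baseline characteristics in each direction, null
    characteristics at equal prevalence, one planted stay dyad and one
    planted swap dyad (members marginally IMPV-leaning, joint
    MC-leaning), and latent co-occurrence classes — fewer, larger ones
    in the improved group; more, smaller ones in the minimal-change
    group.
    """
    catalog = default_catalog()
    prev: dict[str, tuple[float, float]] = {}
    for k, cid in enumerate(catalog.ids):
        p = _BACKGROUND_CYCLE[k % len(_BACKGROUND_CYCLE)]
        prev[cid] = (p, p)
    for cid in STRONG_IMPV:
        prev[cid] = (0.40, 0.10)
    for cid in STRONG_MC:
        prev[cid] = (0.10, 0.40)
    for cid in NULL_CHARACTERISTICS:
        prev[cid] = (0.25, 0.25)
    prev["g06"] = (0.35, 0.30)  # stay-dyad partner
    prev["g07"] = (0.30, 0.28)  # swap-dyad partner (marginally IMPV-leaning)
    for cid in COMMUNITY_IDS:
        prev[cid] = (_COMMUNITY_BASE, _COMMUNITY_BASE)

    # Improved group: two broad co-occurrence communities; minimal-change
    # group: three smaller, tighter ones over the same characteristics
    # (more distinct groupings), marginals balanced across groups.
    comm = COMMUNITY_IDS
    impv_sets = (comm[:7], comm[7:])
    mc_sets = (comm[:5], comm[5:10], comm[10:])
    impv_w = (0.5, 0.5)
    mc_w = (0.34, 0.33, 0.33)
    latent = {
        "IMPV": tuple(
            LatentClass(w, {cid: _boost_for(w) for cid in s})
            for w, s in zip(impv_w, impv_sets)
        ),
        "MC": tuple(
            LatentClass(w, {cid: _boost_for(w) for cid in s})
            for w, s in zip(mc_w, mc_sets)
        ),
    }
    return SimulationScenario(
        catalog=catalog,
        marginal_prevalence=prev,
        planted_dyads=(STAY_DYAD, SWAP_DYAD),
        latent_classes=latent,
        rng_seed=rng_seed,
    )


def threshold_recovery_cohort(
    rng_seed: int,
    n_improved: int = 72,
    n_not_improved: int = 72,
    dz_improved: tuple[float, float] = (0.747, 0.2),
    dz_not_improved: tuple[float, float] = (0.0, 0.2),
) -> Cohort:
    """Cohort built for threshold-derivation studies.

    Lab-improvement status is assigned first; delta-z is then drawn from
    the status-conditional normal, and a consistent lab panel is
    emitted (all three analytes strictly improved, or at least one
    flat/worse).
    """
    rng = np.random.default_rng(rng_seed)
    catalog = CharacteristicCatalog((CatalogEntry("x01", "placeholder trait", "child"),))
    analytes = ("insulin", "triglycerides", "homa_ir")
    medians = {"insulin": 20.0, "triglycerides": 130.0, "homa_ir": 3.5}
    records = []
    for status, n, (mu, sd) in (
        (True, n_improved, dz_improved),
        (False, n_not_improved, dz_not_improved),
    ):
        for r in range(n):
            dz = float(rng.normal(mu, sd))
            z_entry = float(rng.normal(2.8, 0.7))
            first = {a: float(medians[a] * np.exp(rng.normal(0, 0.3))) for a in analytes}
            if status:
                factors = {a: float(rng.uniform(0.60, 0.95)) for a in analytes}
            else:
                factors = {a: float(rng.uniform(0.70, 1.30)) for a in analytes}
                stuck = analytes[int(rng.integers(len(analytes)))]
                factors[stuck] = float(rng.uniform(1.00, 1.40))
            last = {a: first[a] * factors[a] for a in analytes}
            records.append(
                CohortRecord(
                    child_id=f"{'imp' if status else 'not'}_{r:04d}",
                    sex=Sex.MALE if rng.random() < 0.55 else Sex.FEMALE,
                    age_years=float(np.clip(rng.normal(6.5, 2.2), 0.0, 12.0)),
                    characteristics=frozenset(),
                    z_bmi_entry=z_entry,
                    z_bmi_exit=z_entry - dz,
                    labs=LabPanelPair(first=LabValues(**first), last=LabValues(**last)),
                )
            )
    return Cohort(catalog, tuple(records))
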