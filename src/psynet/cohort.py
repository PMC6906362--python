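"""Domain types, validation and file I/O for intervention cohorts.

A cohort is one row per child: demographics, a binary vector over a
catalog of psychological characteristics recorded at the child's first
assessment, entry/exit BMI-for-age z-scores, and (optionally) first/last
values of three laboratory biomarkers (insulin, triglycerides, HOMA-IR).

The module also implements the sex-confound control: removal of any
characteristic whose expression is statistically associated with child
sex (Fisher's exact test on the 2x2 expressed-by-sex table).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import fisher_exact


class CohortValidationError(ValueError):
    """Base class for cohort validation failures."""


class DuplicateChildIdError(CohortValidationError):
    pass


class NonBinaryCellError(CohortValidationError):
    pass


class MissingColumnError(CohortValidationError):
    pass


class UnknownCharacteristicError(CohortValidationError):
    pass


class SingleSexCohortError(CohortValidationError):
    """Sex-association filter requires both sexes to be represented."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Outcome(str, enum.Enum):
    IMPV = "IMPV"
    MC = "MC"


VALID_SOURCES = ("child", "guardian")

#: Reserved (non-characteristic) cohort CSV columns.
RESERVED_COLUMNS = ("child_id", "sex", "age_years", "z_bmi_entry", "z_bmi_exit", "outcome")

#: Lab columns; either all present (possibly with per-row blanks) or all absent.
LAB_COLUMNS = (
    "insulin_first",
    "insulin_last",
    "triglycerides_first",
    "triglycerides_last",
    "homa_ir_first",
    "homa_ir_last",
)


@dataclass(frozen=True)
class CatalogEntry:
    id: str
    label: str
    source: str  # "child" or "guardian"

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise CohortValidationError(
                f"characteristic {self.id!r}: source must be one of {VALID_SOURCES}, got {self.source!r}"
            )


@dataclass(frozen=True)
class CharacteristicCatalog:
    """Ordered catalog of psychological characteristics.

    The study configuration is 28 child-expressed plus 49
    guardian-expressed characteristics (77 total), but any sizes are
    accepted.
    """

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate catalog ids: {dupes}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.entries)

    def counts_by_source(self) -> dict[str, int]:
        counts = {s: 0 for s in VALID_SOURCES}
        for e in self.entries:
            counts[e.source] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cid: str) -> bool:
        return cid in set(self.ids)

    def subset(self, keep: Iterable[str]) -> "CharacteristicCatalog":
        """Return a catalog restricted to ``keep``, preserving order."""
        keep = set(keep)
        unknown = keep - set(self.ids)
        if unknown:
            raise UnknownCharacteristicError(f"unknown characteristic ids: {sorted(unknown)}")
        return CharacteristicCatalog(tuple(e for e in self.entries if e.id in keep))


@dataclass(frozen=True)
class LabValues:
    insulin: float
    triglycerides: float
    homa_ir: float

    def __post_init__(self) -> None:
        for name in ("insulin", "triglycerides", "homa_ir"):
            v = getattr(self, name)
            if not (v > 0):
                raise CohortValidationError(f"lab value {name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class LabPanelPair:
    """First and last recorded values of the three biomarkers."""

    first: LabValues
    last: LabValues


@dataclass(frozen=True)
class CohortRecord:
    child_id: str
    sex: Sex
    age_years: float
    characteristics: frozenset[str]
    z_bmi_entry: float
    z_bmi_exit: float
    labs: Optional[LabPanelPair] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise CohortValidationError(f"child {self.child_id}: age_years must be >= 0")
        import math

        for name in ("z_bmi_entry", "z_bmi_exit"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise CohortValidationError(f"child {self.child_id}: {name} must be finite, got {v}")


@dataclass(frozen=True)
class Cohort:
    catalog: CharacteristicCatalog
    records: tuple[CohortRecord, ...]
    outcome_labels: Optional[dict[str, Outcome]] = None

    def __post_init__(self) -> None:
        ids = [r.child_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateChildIdError(f"duplicate child_id values: {dupes}")
        known = set(self.catalog.ids)
        for r in self.records:
            extra = r.characteristics - known
            if extra:
                raise UnknownCharacteristicError(
                    f"child {r.child_id}: characteristics not in catalog: {sorted(extra)}"
                )
        if self.outcome_labels is not None:
            missing = set(self.outcome_labels) - set(ids)
            if missing:
                raise CohortValidationError(
                    f"outcome labels for unknown child ids: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def with_labels(self, labels: dict[str, Outcome]) -> "Cohort":
        return dataclasses.replace(self, outcome_labels=dict(labels))

    def with_catalog(self, catalog: CharacteristicCatalog) -> "Cohort":
        """Restrict the cohort to a (sub)catalog, dropping other characteristics."""
        keep = set(catalog.ids)
        records = tuple(
            dataclasses.replace(r, characteristics=frozenset(r.characteristics & keep))
            for r in self.records
        )
        return Cohort(catalog, records, self.outcome_labels)

    def group_ids(self, outcome: Outcome) -> list[str]:
        if self.outcome_labels is None:
            raise CohortValidationError("cohort has no outcome labels")
        return [r.child_id for r in self.records if self.outcome_labels.get(r.child_id) == outcome]


# ---------------------------------------------------------------------------
# Catalog I/O (CSV: id,label,source — or JSON list of entries)
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> CharacteristicCatalog:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        entries = tuple(CatalogEntry(d["id"], d.get("label", d["id"]), d["source"]) for d in data)
        return CharacteristicCatalog(entries)
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "source"):
        if col not in df.columns:
            raise MissingColumnError(f"catalog file {path} missing column {col!r}")
    if "label" not in df.columns:
        df["label"] = df["id"]
    entries = tuple(
        CatalogEntry(str(row.id), str(row.label), str(row.source)) for row in df.itertuples()
    )
    return CharacteristicCatalog(entries)


def write_catalog(catalog: CharacteristicCatalog, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps([dataclasses.asdict(e) for e in catalog.entries], indent=1) + "\n"
        )
        return
    df = pd.DataFrame(
        {
            "id": [e.id for e in catalog.entries],
            "label": [e.label for e in catalog.entries],
            "source": [e.source for e in catalog.entries],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _parse_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(path: str | Path, catalog: CharacteristicCatalog | str | Path) -> Cohort:
    """Read a cohort CSV/TSV against a characteristic catalog.

    The file must contain ``child_id``, ``sex``, ``age_years``,
    ``z_bmi_entry``, ``z_bmi_exit`` and one 0/1 column per catalog id.
    Lab columns are optional as a block; per-row blanks yield absent labs.
    Any column that is neither reserved, a lab column, nor a catalog id
    raises :class:`UnknownCharacteristicError`.
    """
    path = Path(path)
    if not isinstance(catalog, CharacteristicCatalog):
        catalog = read_catalog(catalog)
    df = pd.read_csv(path, sep=_parse_sep(path), dtype={"child_id": str})

    mandatory = ("child_id", "sex", "age_years", "z_bmi_entry", "z_bmi_exit")
    for col in mandatory:
        if col not in df.columns:
            raise MissingColumnError(f"cohort file {path} missing mandatory column {col!r}")

    known = set(RESERVED_COLUMNS) | set(LAB_COLUMNS) | set(catalog.ids)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise UnknownCharacteristicError(
            f"cohort file {path}: unknown characteristic columns {unknown}"
        )
    missing_chars = [c for c in catalog.ids if c not in df.columns]
    if missing_chars:
        raise MissingColumnError(
            f"cohort file {path} missing characteristic columns {missing_chars}"
        )

    has_labs = all(c in df.columns for c in LAB_COLUMNS)

    records = []
    labels: dict[str, Outcome] = {}
    for idx, row in df.iterrows():
        cid = str(row["child_id"])
        chars = set()
        for c in catalog.ids:
            v = row[c]
            if pd.isna(v) or float(v) not in (0.0, 1.0):
                raise NonBinaryCellError(
                    f"cohort file {path}: row {idx} column {c!r} has non-binary value {v!r}"
                )
            if float(v) == 1.0:
                chars.add(c)
        labs = None
        if has_labs and not any(pd.isna(row[c]) for c in LAB_COLUMNS):
            labs = LabPanelPair(
                first=LabValues(
                    float(row["insulin_first"]),
                    float(row["triglycerides_first"]),
                    float(row["homa_ir_first"]),
                ),
                last=LabValues(
                    float(row["insulin_last"]),
                    float(row["triglycerides_last"]),
                    float(row["homa_ir_last"]),
                ),
            )
        records.append(
            CohortRecord(
                child_id=cid,
                sex=Sex(str(row["sex"])),
                age_years=float(row["age_years"]),
                characteristics=frozenset(chars),
                z_bmi_entry=float(row["z_bmi_entry"]),
                z_bmi_exit=float(row["z_bmi_exit"]),
                labs=labs,
            )
        )
        if "outcome" in df.columns and not pd.isna(row["outcome"]):
            labels[cid] = Outcome(str(row["outcome"]))

    return Cohort(catalog, tuple(records), labels or None)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    has_labs = any(r.labs is not None for r in cohort.records)
    has_labels = cohort.outcome_labels is not None
    rows = []
    for r in cohort.records:
        row: dict = {
            "child_id": r.child_id,
            "sex": r.sex.value,
            "age_years": r.age_years,
            "z_bmi_entry": r.z_bmi_entry,
            "z_bmi_exit": r.z_bmi_exit,
        }
        if has_labs:
            if r.labs is None:
                row.update({c: "" for c in LAB_COLUMNS})
            else:
                row.update(
                    {
                        "insulin_first": r.labs.first.insulin,
                        "insulin_last": r.labs.last.insulin,
                        "triglycerides_first": r.labs.first.triglycerides,
                        "triglycerides_last": r.labs.last.triglycerides,
                        "homa_ir_first": r.labs.first.homa_ir,
                        "homa_ir_last": r.labs.last.homa_ir,
                    }
                )
        if has_labels:
            lab = cohort.outcome_labels.get(r.child_id)
            row["outcome"] = lab.value if lab is not None else ""
        for c in cohort.catalog.ids:
            row[c] = int(c in r.characteristics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_parse_sep(path), index=False)


# ---------------------------------------------------------------------------
# Sex-confound filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexFilterResult:
    retained: CharacteristicCatalog
    removed: tuple[tuple[str, float], ...]  # (id, p-value), p <= alpha
    p_values: dict[str, float]
    warnings: tuple[str, ...]


def sex_association_filter(cohort: Cohort, alpha: float = 0.05) -> SexFilterResult:
    """Remove characteristics associated with child sex.

    For each characteristic the 2x2 table (expressed x sex) is tested
    with Fisher's exact test (two-sided). Characteristics with
    p <= ``alpha`` are removed; retained order is preserved. A
    characteristic expressed by no child gets p = 1 and a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n_male = sum(r.sex is Sex.MALE for r in cohort.records)
    n_female = sum(r.sex is Sex.FEMALE for r in cohort.records)
    if n_male == 0 or n_female == 0:
        raise SingleSexCohortError(
            "sex-association filter requires at least one record of each sex"
        )
    p_values: dict[str, float] = {}
    warnings: list[str] = []
    removed: list[tuple[str, float]] = []
    for cid in cohort.catalog.ids:
        k_male = sum(cid in r.characteristics for r in cohort.records if r.sex is Sex.MALE)
        k_female = sum(cid in r.characteristics for r in cohort.records if r.sex is Sex.FEMALE)
        if k_male + k_female == 0:
            p = 1.0
            warnings.append(f"characteristic {cid} expressed by no child; retained with p=1")
        else:
            table = [[k_male, k_female], [n_male - k_male, n_female - k_female]]
            p = float(fisher_exact(table, alternative="two-sided").pvalue)
        p_values[cid] = p
        if p <= alpha:
            removed.append((cid, p))
    retained = cohort.catalog.subset(set(cohort.catalog.ids) - {c for c, _ in removed})
    return SexFilterResult(retained, tuple(removed), p_values, tuple(warnings))
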