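"""Tabular input/output and cohort validation.

All on-disk formats are plain tab-separated UTF-8 text with a header row:

* participant table: ``participant_id age sex bmi serum_d0 serum_d1``
* counts: first column ``gene_id``, remaining columns are sample ids;
  companion sample sheet ``sample_id participant_id timepoint``
* gene annotation: ``gene_id symbol biotype has_position``

Numeric fields accept both ``.`` and ``,`` as decimal separator, because the
published participant table itself mixes the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TIMEPOINTS = ("d0", "d1")

__all__ = [
    "ParticipantRecord",
    "CohortTable",
    "CountMatrix",
    "GeneAnnotation",
    "CohortValidationError",
    "read_participant_table",
    "read_counts",
    "read_annotation",
    "read_table",
    "write_table",
    "load_vitdpas_table1",
]


class CohortValidationError(ValueError):
    """Raised when a table violates the cohort structure contract."""


def _num(value) -> float:
    """Parse a decimal number accepting ',' or '.' as separator."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip().replace(",", ".")
    try:
        return float(text)
    except ValueError as exc:
        raise CohortValidationError(f"cannot parse number: {value!r}") from exc


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: demographics plus serum 25(OH)D3 (ng/ml) at day 0 / day 1."""

    participant_id: str
    age: int
    sex: str
    bmi: float
    serum_d0: float
    serum_d1: float

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise CohortValidationError(f"sex must be F or M, got {self.sex!r}")
        for name in ("age", "bmi", "serum_d0", "serum_d1"):
            if getattr(self, name) <= 0:
                raise CohortValidationError(
                    f"{name} must be positive for participant {self.participant_id}"
                )

    @property
    def serum_ratio(self) -> float:
        return self.serum_d1 / self.serum_d0


@dataclass
class CohortTable:
    """Ordered collection of participants with unique ids."""

    cohort_name: str
    records: list[ParticipantRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.participant_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(f"duplicate participant ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "bmi": [r.bmi for r in self.records],
                "serum_d0": [r.serum_d0 for r in self.records],
                "serum_d1": [r.serum_d1 for r in self.records],
            }
        )


@dataclass
class GeneAnnotation:
    """Per-gene annotation: symbol, biotype, genomic-position availability."""

    frame: pd.DataFrame  # indexed by gene_id

    def __post_init__(self):
        if not self.frame.index.is_unique:
            raise CohortValidationError("gene ids in annotation are not unique")
        missing = {"symbol", "biotype", "has_position"} - set(self.frame.columns)
        if missing:
            raise CohortValidationError(f"annotation missing columns: {sorted(missing)}")

    def covers(self, gene_ids: Iterable[str]) -> bool:
        return set(gene_ids) <= set(self.frame.index)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a paired (d0, d1) sample design.

    ``counts`` is a genes-by-samples DataFrame; ``sample_map`` maps each
    sample id to ``(participant_id, timepoint)``. Every participant must
    contribute exactly one d0 and one d1 sample.
    """

    counts: pd.DataFrame
    sample_map: pd.DataFrame  # indexed by sample_id: participant_id, timepoint

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise CohortValidationError("gene ids are not unique")
        if list(self.counts.columns) != list(self.sample_map.index):
            self.sample_map = self.sample_map.loc[list(self.counts.columns)]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise CohortValidationError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise CohortValidationError("non-integer counts")
        bad_tp = set(self.sample_map["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise CohortValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        per = self.sample_map.groupby("participant_id")["timepoint"].apply(
            lambda s: sorted(s)
        )
        unpaired = [p for p, tps in per.items() if tps != ["d0", "d1"]]
        if unpaired:
            raise CohortValidationError(
                f"participants without exactly one d0 and one d1 sample: {unpaired}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def participant_ids(self) -> list[str]:
        seen: list[str] = []
        for pid in self.sample_map["participant_id"]:
            if pid not in seen:
                seen.append(pid)
        return seen

    def samples_at(self, timepoint: str) -> list[str]:
        if timepoint not in TIMEPOINTS:
            raise CohortValidationError(f"unknown timepoint {timepoint!r}")
        return list(self.sample_map.index[self.sample_map["timepoint"] == timepoint])

    def sample_of(self, participant_id: str, timepoint: str) -> str:
        m = self.sample_map
        hit = m.index[
            (m["participant_id"] == participant_id) & (m["timepoint"] == timepoint)
        ]
        if len(hit) != 1:
            raise CohortValidationError(
                f"no unique {timepoint} sample for participant {participant_id}"
            )
        return hit[0]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PARTICIPANT_COLUMNS = ["participant_id", "age", "sex", "bmi", "serum_d0", "serum_d1"]


def read_participant_table(path: str | Path, cohort_name: str | None = None) -> CohortTable:
    """Read a participant TSV into a validated :class:`CohortTable`.

    Decimal commas are accepted anywhere a number is expected (the published
    table prints ``15,2`` for one serum value).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"participant table missing columns: {sorted(missing)}")
    records = [
        ParticipantRecord(
            participant_id=str(row["participant_id"]).strip(),
            age=int(round(_num(row["age"]))),
            sex=str(row["sex"]).strip(),
            bmi=_num(row["bmi"]),
            serum_d0=_num(row["serum_d0"]),
            serum_d1=_num(row["serum_d1"]),
        )
        for _, row in df.iterrows()
    ]
    return CohortTable(cohort_name or path.stem, records)


def read_counts(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample sheet."""
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
    missing = {"sample_id", "participant_id", "timepoint"} - set(sheet.columns)
    if missing:
        raise CohortValidationError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    absent = set(counts.columns) - set(sheet.index)
    if absent:
        raise CohortValidationError(f"samples without sheet entry: {sorted(absent)}")
    return CountMatrix(counts=counts, sample_map=sheet.loc[list(counts.columns)])


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["has_position"] = df["has_position"].astype(str).str.lower().isin(
        ["true", "1", "yes"]
    )
    return GeneAnnotation(df)


def write_table(obj: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a result table as TSV with a stable column order.

    Floats are rendered with :func:`repr` precision so that a write/read
    round-trip reproduces every field exactly and re-runs are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj.to_csv(path, sep="\t", index=index, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_vitdpas_table1() -> CohortTable:
    """The packaged 45-participant intervention-trial table (VitDPAS)."""
    ref = resources.files("vdindex.data") / "vitdpas_table1.tsv"
    with resources.as_file(ref) as path:
        return read_participant_table(path, cohort_name="VitDPAS")
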