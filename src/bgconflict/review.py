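"""Study-level literature review of between-group conflict outcomes.

Each reviewed study contributes one binary data point: did numerically
larger groups win contests more often than chance in that system?  Studies
are stratified by contest type — defense of a discrete resource patch versus
defense of a territory.  This module reads and validates such a table,
computes the marginal proportions, and ships a synthetic 33-study fixture
whose marginals match the published review (13 resource studies of which 9
report a larger-group advantage; 20 territorial studies of which 16 do).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "StudyRecord",
    "ReviewSummary",
    "read_review_table",
    "write_review_table",
    "summarize_review",
    "build_review_fixture",
    "fixture_path",
]

REVIEW_COLUMNS = ["study_id", "species", "mean_group_size", "contest_type", "larger_wins"]
CONTEST_TYPES = ("resource", "territorial")
OUTCOMES = ("yes", "no")


class ReviewSchemaError(ValueError):
    """Raised when a review table violates the required schema or codings."""


@dataclass(frozen=True)
class StudyRecord:
    """One reviewed study as a single binary data point."""

    study_id: str
    species: str
    mean_group_size: float
    contest_type: str  # "resource" | "territorial"
    larger_wins: str  # "yes" | "no"

    def __post_init__(self) -> None:
        if self.contest_type not in CONTEST_TYPES:
            raise ReviewSchemaError(
                f"contest_type must be one of {CONTEST_TYPES}, got {self.contest_type!r}"
            )
        if self.larger_wins not in OUTCOMES:
            raise ReviewSchemaError(
                f"larger_wins must be one of {OUTCOMES}, got {self.larger_wins!r}"
            )
        if not self.mean_group_size > 0:
            raise ReviewSchemaError("mean_group_size must be positive")


@dataclass(frozen=True)
class ReviewSummary:
    """Counts and percentages of the review marginals.

    Percentages are 100 x count ratios, rounded to one decimal place.
    """

    n_total: int
    n_resource: int
    n_territorial: int
    n_yes_total: int
    n_yes_resource: int
    n_yes_territorial: int
    pct_yes_total: float
    pct_yes_resource: float
    pct_yes_territorial: float
    pct_resource: float
    pct_territorial: float

    def to_long_table(self) -> pd.DataFrame:
        """Stacked-bar style long table: contest_type x outcome with counts/pcts."""
        rows = []
        for ctype, n_c, n_yes in [
            ("resource", self.n_resource, self.n_yes_resource),
            ("territorial", self.n_territorial, self.n_yes_territorial),
        ]:
            for outcome, count in [("yes", n_yes), ("no", n_c - n_yes)]:
                rows.append(
                    {
                        "contest_type": ctype,
                        "outcome": outcome,
                        "count": count,
                        "pct": round(100.0 * count / n_c, 1) if n_c else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


def read_review_table(path: Union[str, Path]) -> list[StudyRecord]:
    """Read and validate a review CSV into study records.

    Bad codings are rejected with the offending row numbers (1-based data
    rows); a missing column raises a schema error; an empty table returns an
    empty list with a warning.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "species": str})
    missing = [c for c in REVIEW_COLUMNS if c not in df.columns]
    if missing:
        raise ReviewSchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        warnings.warn(f"review table {path} contains no studies", stacklevel=2)
        return []
    bad_rows = []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                StudyRecord(
                    study_id=str(row.study_id),
                    species=str(row.species),
                    mean_group_size=float(row.mean_group_size),
                    contest_type=str(row.contest_type),
                    larger_wins=str(row.larger_wins),
                )
            )
        except (ReviewSchemaError, ValueError):
            bad_rows.append(i)
    if bad_rows:
        raise ReviewSchemaError(
            f"invalid coding in row(s) {', '.join(map(str, bad_rows))} "
            f"(contest_type must be in {CONTEST_TYPES}, larger_wins in {OUTCOMES})"
        )
    return records


def write_review_table(records: Iterable[StudyRecord], path: Union[str, Path]) -> None:
    """Write study records to CSV under the canonical schema."""
    pd.DataFrame([vars(r) for r in records], columns=REVIEW_COLUMNS).to_csv(
        path, index=False
    )


def summarize_review(records: Sequence[StudyRecord]) -> ReviewSummary:
    """Aggregate binary study outcomes into the review marginals."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty review")
    n_total = len(records)
    n_resource = sum(r.contest_type == "resource" for r in records)
    n_territorial = n_total - n_resource
    n_yes_resource = sum(
        r.contest_type == "resource" and r.larger_wins == "yes" for r in records
    )
    n_yes_territorial = sum(
        r.contest_type == "territorial" and r.larger_wins == "yes" for r in records
    )
    n_yes_total = n_yes_resource + n_yes_territorial

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else float("nan")

    return ReviewSummary(
        n_total=n_total,
        n_resource=n_resource,
        n_territorial=n_territorial,
        n_yes_total=n_yes_total,
        n_yes_resource=n_yes_resource,
        n_yes_territorial=n_yes_territorial,
        pct_yes_total=pct(n_yes_total, n_total),
        pct_yes_resource=pct(n_yes_resource, n_resource),
        pct_yes_territorial=pct(n_yes_territorial, n_territorial),
        pct_resource=pct(n_resource, n_total),
        pct_territorial=pct(n_territorial, n_total),
    )


def build_review_fixture() -> list[StudyRecord]:
    """Synthetic 33-study table reproducing the published review marginals.

    Only the marginal counts are encoded — 13 resource studies (9 yes, 4 no)
    and 20 territorial studies (16 yes, 4 no); species and group sizes are
    placeholders, as the per-study assignments are not part of the printed
    summary.
    """
    spec = [
        ("resource", "yes", 9),
        ("resource", "no", 4),
        ("territorial", "yes", 16),
        ("territorial", "no", 4),
    ]
    records = []
    idx = 0
    for ctype, outcome, count in spec:
        for _ in range(count):
            idx += 1
            records.append(
                StudyRecord(
                    study_id=f"S{idx:02d}",
                    species=f"placeholder_sp_{idx:02d}",
                    mean_group_size=20.0,
                    contest_type=ctype,
                    larger_wins=outcome,
                )
            )
    return records


def fixture_path() -> Path:
    """Path of the packaged synthetic review CSV (written by the fixture builder)."""
    return Path(resources.files("bgconflict.data") / "review_synthetic.csv")
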