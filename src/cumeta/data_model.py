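"""Domain types, validation and CSV I/O for two-arm binary-outcome trials.

The central object is the :class:`TrialRecord`: one randomized comparison of
a treated (experimental) arm against a control arm, each summarised by its
number of patients and its number of failures.  Trials are totally ordered by
``order_key`` (publication date or an explicit integer rank) so that they can
be absorbed one at a time in a cumulative meta-analysis.

A packaged fixture, ``knee13``, ships the 13 randomized trials comparing
patient-specific versus conventional instrumentation in total knee
replacement (failure = coronal alignment more than 3 degrees from neutral);
it is the worked example used throughout the documentation and tests.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence, Union

OrderKey = Union[date, int]

__all__ = [
    "TrialRecord",
    "BetaParams",
    "EvidenceState",
    "CumulativeRow",
    "parse_trials",
    "load_fixture",
    "write_rows",
    "TrialValidationError",
]


class TrialValidationError(ValueError):
    """Raised when trial input fails validation; carries row context."""


@dataclass(frozen=True)
class TrialRecord:
    """One randomized two-arm comparison with binary failure counts."""

    trial_id: str
    label: str
    order_key: OrderKey
    n_control: int
    events_control: int
    n_treated: int
    events_treated: int

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise TrialValidationError("trial_id must be non-empty")
        for arm in ("control", "treated"):
            n = getattr(self, f"n_{arm}")
            ev = getattr(self, f"events_{arm}")
            if n <= 0:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: n_{arm} must be positive, got {n}"
                )
            if not 0 <= ev <= n:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: events_{arm}={ev} outside [0, n_{arm}={n}]"
                )

    @property
    def n_total(self) -> int:
        """Total enrolment of the trial (both arms)."""
        return self.n_control + self.n_treated

    @property
    def planned_sample_size(self) -> int:
        """Derived metadata mirroring the trial's own total enrolment."""
        return self.n_total


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of a beta law for one arm's failure probability.

    ``alpha`` counts failures (plus prior pseudo-failures), ``beta`` counts
    successes.  Conjugacy with the binomial likelihood means every prior and
    posterior in the model is of this form.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


UNIFORM = BetaParams(1.0, 1.0)


@dataclass(frozen=True)
class EvidenceState:
    """Both arms' posteriors after absorbing the first ``k`` trials."""

    k: int
    control: BetaParams
    treated: BetaParams
    cum_n_control: int
    cum_events_control: int
    cum_n_treated: int
    cum_events_treated: int
    trial_id: str | None = None


@dataclass(frozen=True)
class CumulativeRow:
    """One row of the cumulative-evidence table (one per absorbed trial).

    Sign conventions: ``rd_mean`` and its credible interval are treated minus
    control (negative favours the experimental treatment), while
    ``prob_exceeds[d]`` is Pr(p_control - p_treated > d), the probability the
    experimental arm beats control by more than ``d``.  ``predictive[d]`` is
    the posterior-predictive probability that a future sample shows an
    observed control-minus-treated failure-rate difference of at least ``d``.
    """

    trial_id: str
    mean_control: float
    mean_treated: float
    rd_mean: float
    rd_cri_low: float
    rd_cri_high: float
    prob_exceeds: Mapping[float, float] = field(default_factory=dict)
    predictive: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rd_cri_low <= self.rd_mean <= self.rd_cri_high:
            raise ValueError(
                f"row {self.trial_id!r}: CrI ({self.rd_cri_low}, {self.rd_cri_high}) "
                f"does not bracket mean {self.rd_mean}"
            )
        for name in ("prob_exceeds", "predictive"):
            for d, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"row {self.trial_id!r}: {name}[{d}]={p} outside [0,1]")


_COLUMNS = (
    "trial_id",
    "label",
    "date",  # or "rank"
    "n_control",
    "events_control",
    "n_treated",
    "events_treated",
)


def _parse_order_key(row: Mapping[str, str], rownum: int) -> OrderKey:
    if "date" in row and row["date"]:
        try:
            return date.fromisoformat(row["date"].strip())
        except ValueError as exc:
            raise TrialValidationError(f"row {rownum}: bad date {row['date']!r}: {exc}") from exc
    if "rank" in row and row["rank"]:
        try:
            return int(row["rank"])
        except ValueError as exc:
            raise TrialValidationError(f"row {rownum}: bad rank {row['rank']!r}") from exc
    raise TrialValidationError(f"row {rownum}: needs a 'date' (ISO-8601) or 'rank' column value")


def _parse_count(row: Mapping[str, str], col: str, rownum: int) -> int:
    raw = (row.get(col) or "").strip()
    try:
        value = int(raw)
    except ValueError as exc:
        raise TrialValidationError(f"row {rownum}: field {col!r}={raw!r} is not an integer") from exc
    if value < 0:
        raise TrialValidationError(f"row {rownum}: field {col!r}={value} is negative")
    return value


def parse_trials(source: Union[str, IO[str]]) -> list[TrialRecord]:
    """Read trials from a CSV path or text stream, sorted by order key.

    The header must name ``trial_id, label, date`` (ISO-8601) or ``rank``,
    and the four count columns.  Ties on the order key keep file order, then
    break on ``trial_id``.  Duplicate trial ids are rejected.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as handle:
            return parse_trials(handle)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise TrialValidationError("empty input: CSV header row is required")
    missing = {"trial_id", "label", "n_control", "events_control", "n_treated", "events_treated"} - set(
        reader.fieldnames
    )
    if missing:
        raise TrialValidationError(f"missing required columns: {sorted(missing)}")
    if "date" not in reader.fieldnames and "rank" not in reader.fieldnames:
        raise TrialValidationError("an order column is required: 'date' or 'rank'")

    records: list[tuple[OrderKey, int, str, TrialRecord]] = []
    seen: set[str] = set()
    for i, row in enumerate(reader):
        rownum = i + 2  # 1-based, after header
        trial_id = (row.get("trial_id") or "").strip()
        if not trial_id:
            raise TrialValidationError(f"row {rownum}: empty trial_id")
        if trial_id in seen:
            raise TrialValidationError(f"row {rownum}: duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        try:
            record = TrialRecord(
                trial_id=trial_id,
                label=(row.get("label") or "").strip(),
                order_key=_parse_order_key(row, rownum),
                n_control=_parse_count(row, "n_control", rownum),
                events_control=_parse_count(row, "events_control", rownum),
                n_treated=_parse_count(row, "n_treated", rownum),
                events_treated=_parse_count(row, "events_treated", rownum),
            )
        except TrialValidationError:
            raise
        except ValueError as exc:
            raise TrialValidationError(f"row {rownum}: {exc}") from exc
        records.append((record.order_key, i, trial_id, record))

    records.sort(key=lambda item: (item[0], item[1], item[2]))
    return [record for *_, record in records]


def load_fixture(name: str = "knee13") -> list[TrialRecord]:
    """Return a packaged dataset; ``knee13`` is the 13-trial knee example."""
    path = resources.files("cumeta.data").joinpath(f"{name}.csv")
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise KeyError(f"unknown fixture {name!r}") from exc
    return parse_trials(io.StringIO(text))


def _format_delta(d: float) -> str:
    return format(d, "g")


def write_rows(rows: Sequence[CumulativeRow], sink: Union[str, IO[str]], precision: int = 6) -> None:
    """Write cumulative rows as CSV with a fixed column order.

    Threshold-keyed probability maps become one column per threshold, named
    ``pr_exceeds_<d>`` and ``pred_ge_<d>``; all rows must share thresholds.
    """
    if not rows:
        raise ValueError("write_rows requires at least one row")
    if isinstance(sink, str):
        with open(sink, "w", newline="", encoding="utf-8") as handle:
            write_rows(rows, handle, precision=precision)
        return

    deltas = list(rows[0].prob_exceeds)
    pred_deltas = list(rows[0].predictive)
    header = (
        ["trial_id", "mean_control", "mean_treated", "rd_mean", "rd_cri_low", "rd_cri_high"]
        + [f"pr_exceeds_{_format_delta(d)}" for d in deltas]
        + [f"pred_ge_{_format_delta(d)}" for d in pred_deltas]
    )
    writer = csv.writer(sink)
    writer.writerow(header)
    fmt = f"{{:.{precision}f}}".format
    for row in rows:
        if list(row.prob_exceeds) != deltas or list(row.predictive) != pred_deltas:
            raise ValueError(f"row {row.trial_id!r} has inconsistent thresholds")
        writer.writerow(
            [row.trial_id]
            + [fmt(v) for v in (row.mean_control, row.mean_treated, row.rd_mean, row.rd_cri_low, row.rd_cri_high)]
            + [fmt(row.prob_exceeds[d]) for d in deltas]
            + [fmt(row.predictive[d]) for d in pred_deltas]
        )


def parse_rows(source: Union[str, IO[str]]) -> list[CumulativeRow]:
    """Read back a table written by :func:`write_rows` (round-trip partner)."""
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as handle:
            return parse_rows(handle)
    reader = csv.DictReader(source)
    rows: list[CumulativeRow] = []
    fieldnames = reader.fieldnames or []
    exceed_cols = [c for c in fieldnames if c.startswith("pr_exceeds_")]
    pred_cols = [c for c in fieldnames if c.startswith("pred_ge_")]
    for raw in reader:
        rows.append(
            CumulativeRow(
                trial_id=raw["trial_id"],
                mean_control=float(raw["mean_control"]),
                mean_treated=float(raw["mean_treated"]),
                rd_mean=float(raw["rd_mean"]),
                rd_cri_low=float(raw["rd_cri_low"]),
                rd_cri_high=float(raw["rd_cri_high"]),
                prob_exceeds={float(c.removeprefix("pr_exceeds_")): float(raw[c]) for c in exceed_cols},
                predictive={float(c.removeprefix("pred_ge_")): float(raw[c]) for c in pred_cols},
            )
        )
    return rows


def check_sorted(trials: Iterable[TrialRecord]) -> None:
    """Raise if trials are not ascending in order_key."""
    prev: OrderKey | None = None
    for t in trials:
        if prev is not None and t.order_key < prev:  # type: ignore[operator]
            raise ValueError(f"trials not sorted by order_key at {t.trial_id!r}")
        prev = t.order_key
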