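"""File input/output and the packaged application datasets.

Complete samples are plain text: one positive number per line (or several per
line, whitespace- or comma-separated).  Censored samples are two-column CSV
with a ``time,event`` header, event 1 = observed, 0 = right-censored.  Lines
starting with ``#`` are comments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

from .calibration import CriticalTable
from .censored import CensoredSample
from .core import SurvivalSample

__all__ = [
    "read_survival_file",
    "write_survival_file",
    "DatasetFixture",
    "list_datasets",
    "load_dataset",
    "reference_critical_table",
]

Sample = Union[SurvivalSample, CensoredSample]


class ParseError(ValueError):
    """A data file could not be parsed; the message carries the line number."""


def _tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_survival_file(path: str | Path) -> Sample:
    """Read a complete or censored sample, auto-detecting the format.

    A ``time,event`` header (or two columns per row) yields a CensoredSample,
    a single column a SurvivalSample.  Raises ParseError with the offending
    line number on bad input.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, _tokens(line)))
    if not rows:
        raise ParseError(f"{path}: no data rows found")

    header = [t.lower() for t in rows[0][1]]
    censored = header[:2] == ["time", "event"]
    if censored:
        rows = rows[1:]
        times, events = [], []
        for lineno, toks in rows:
            if len(toks) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'time,event', got {toks!r}")
            try:
                t = float(toks[0])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric time {toks[0]!r}") from None
            if toks[1] not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: event indicator must be 0 or 1")
            if t <= 0:
                raise ParseError(f"{path}:{lineno}: times must be positive")
            times.append(t)
            events.append(int(toks[1]))
        return CensoredSample(times, events)

    values: list[float] = []
    for lineno, toks in rows:
        for tok in toks:
            try:
                v = float(tok)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value {tok!r}") from None
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative lifetime {v}")
            values.append(v)
    return SurvivalSample(values)


def write_survival_file(sample: Sample, path: str | Path) -> None:
    """Write a sample in the same dialect read_survival_file accepts."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if isinstance(sample, CensoredSample):
            writer = csv.writer(fh)
            writer.writerow(["time", "event"])
            for t, d in zip(sample.times, sample.events):
                writer.writerow([f"{t:.17g}", d])
        else:
            fh.write("\n".join(f"{t:.17g}" for t in sample.times) + "\n")


@dataclass(frozen=True)
class DatasetFixture:
    """A packaged application dataset."""

    name: str
    description: str
    filename: str
    n: int
    n_events: int | None  # None for complete data


_FIXTURES = {
    "leukemia": DatasetFixture(
        name="leukemia",
        description="Ages (years) of 40 leukemia patients; complete data",
        filename="leukemia_ages.txt",
        n=40,
        n_events=None,
    ),
    "liver_complete": DatasetFixture(
        name="liver_complete",
        description="Survival (days) of 39 liver cancer patients; complete data",
        filename="liver_cancer_complete.txt",
        n=39,
        n_events=None,
    ),
    "liver_censored": DatasetFixture(
        name="liver_censored",
        description="Survival (days) of 51 liver cancer patients; 12 right-censored",
        filename="liver_cancer_censored.csv",
        n=51,
        n_events=39,
    ),
    "lung_cancer": DatasetFixture(
        name="lung_cancer",
        description="Survival (weeks) of 61 unresectable lung cancer patients; "
        "28 right-censored",
        filename="lung_cancer_censored.csv",
        n=61,
        n_events=33,
    ),
}


def list_datasets() -> list[DatasetFixture]:
    """All packaged application datasets."""
    return list(_FIXTURES.values())


def _data_path(filename: str):
    return resources.files("nbu2test.data").joinpath(filename)


def load_dataset(name: str) -> Sample:
    """Load a packaged dataset by name (see list_datasets)."""
    try:
        fixture = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown dataset {name!r}; available: {sorted(_FIXTURES)}") from None
    with resources.as_file(_data_path(fixture.filename)) as p:
        sample = read_survival_file(p)
    expected_n = fixture.n
    got_n = sample.l if isinstance(sample, CensoredSample) else sample.n
    assert got_n == expected_n, f"fixture {name} has {got_n} records, expected {expected_n}"
    if fixture.n_events is not None:
        assert isinstance(sample, CensoredSample)
        assert sample.n_events == fixture.n_events
    return sample


def reference_critical_table(s: float, censored: bool = False) -> CriticalTable:
    """The published percentile-point tables, shipped for regression comparison.

    Available for s in {0.4, 0.6}; the censored tables are reference-only
    (their generating mechanism is not fully specified in the source they
    were transcribed from).
    """
    key = {0.4: "04", 0.6: "06"}.get(s)
    if key is None:
        raise KeyError("reference tables exist only for s = 0.4 and s = 0.6")
    stem = "reference_percentiles_censored_" if censored else "reference_percentiles_"
    text = _data_path(f"{stem}s{key}.tsv").read_text()
    return CriticalTable.from_tsv(text, s=s, n_reps=10_000)
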