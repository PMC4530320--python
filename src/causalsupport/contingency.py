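"""Contingency-table containers for two candidate causes and a constant background.

The basic unit of evidence is a count of effect-present / effect-absent trials
for one configuration of the two candidate causes (target and alternative),
observed against an ever-present background cause.  A :class:`ContingencyDataset`
collects one cell per distinct configuration; configurations that were never
presented are simply absent from the dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CauseConfig",
    "ContingencyCell",
    "ContingencyDataset",
    "conditional_probability",
    "read_contingency_csv",
    "write_contingency_csv",
]

CSV_COLUMNS = ("target_present", "alternative_present", "n_effect", "n_no_effect")


@dataclass(frozen=True, order=True)
class CauseConfig:
    """Presence pattern of the candidate causes on a trial.

    The background cause is always present; only the target and alternative
    candidate causes vary across trials.
    """

    target_present: int
    alternative_present: int
    background_present: int = 1

    def __post_init__(self) -> None:
        for name in ("target_present", "alternative_present"):
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {value!r}")
        if self.background_present != 1:
            raise ValueError("background_present must be 1: the background cause is always present")


@dataclass(frozen=True)
class ContingencyCell:
    """Effect / no-effect counts for one cause configuration."""

    config: CauseConfig
    n_effect: int
    n_no_effect: int

    def __post_init__(self) -> None:
        for name in ("n_effect", "n_no_effect"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def n_trials(self) -> int:
        return self.n_effect + self.n_no_effect


def conditional_probability(cell: ContingencyCell) -> float:
    """Observed probability of the effect in this configuration, n_e+ / n_trials."""
    if cell.n_trials == 0:
        raise ValueError(
            "conditional probability undefined for a cell with zero trials "
            f"(config {cell.config})"
        )
    return cell.n_effect / cell.n_trials


@dataclass(frozen=True)
class ContingencyDataset:
    """A set of contingency cells, at most one per cause configuration."""

    cells: tuple[ContingencyCell, ...]
    label: str = ""

    def __post_init__(self) -> None:
        cells = tuple(self.cells)
        object.__setattr__(self, "cells", cells)
        seen: set[CauseConfig] = set()
        for cell in cells:
            if cell.config in seen:
                raise ValueError(f"duplicate configuration {cell.config} in dataset {self.label!r}")
            seen.add(cell.config)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def n_trials(self) -> int:
        return sum(cell.n_trials for cell in self.cells)

    def get(self, target_present: int, alternative_present: int) -> Optional[ContingencyCell]:
        config = CauseConfig(target_present, alternative_present)
        for cell in self.cells:
            if cell.config == config:
                return cell
        return None

    def counts(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Mapping (target, alternative) -> (n_effect, n_no_effect)."""
        return {
            (c.config.target_present, c.config.alternative_present): (c.n_effect, c.n_no_effect)
            for c in self.cells
        }

    def relabel(self, label: str) -> "ContingencyDataset":
        return dataclasses.replace(self, label=label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target_present": c.config.target_present,
                "alternative_present": c.config.alternative_present,
                "n_effect": c.n_effect,
                "n_no_effect": c.n_no_effect,
            }
            for c in sorted(self.cells, key=lambda c: c.config)
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    @classmethod
    def from_counts(
        cls,
        counts: dict[tuple[int, int], tuple[int, int]] | Iterable[tuple[tuple[int, int], tuple[int, int]]],
        label: str = "",
    ) -> "ContingencyDataset":
        items = counts.items() if isinstance(counts, dict) else counts
        cells = tuple(
            ContingencyCell(CauseConfig(t, a), int(ne), int(nn)) for (t, a), (ne, nn) in items
        )
        return cls(cells=cells, label=label)


def write_contingency_csv(dataset: ContingencyDataset, path) -> None:
    """Write a dataset as long-format CSV (one row per configuration)."""
    dataset.to_frame().to_csv(path, index=False)


def read_contingency_csv(path, label: str = "") -> ContingencyDataset:
    """Read a long-format contingency CSV; rows are validated individually."""
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"contingency CSV {path} is missing columns {missing}")
    cells = []
    seen: set[CauseConfig] = set()
    for idx, row in frame.iterrows():
        try:
            values = [int(row[c]) for c in CSV_COLUMNS]
            if any(float(row[c]) != v for c, v in zip(CSV_COLUMNS, values)):
                raise ValueError("non-integer count")
            config = CauseConfig(values[0], values[1])
            cell = ContingencyCell(config, values[2], values[3])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed row {idx} in {path}: {exc}") from exc
        if config in seen:
            raise ValueError(f"duplicate configuration {config} at row {idx} in {path}")
        seen.add(config)
        cells.append(cell)
    return ContingencyDataset(cells=tuple(cells), label=label or str(path))
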