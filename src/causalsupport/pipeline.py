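"""Model predictions for every scenario of the packaged design, and their
ordinal comparison with the packaged human-judgment summaries.

A *scenario* is one target cause (confounded or interacting pair) in one phase
for one group.  For each scenario the model produces causal support (structure
confidence), the posterior-mean strength scaled to [0, 100], and the posterior
entropy (uncertainty).  The comparison report lines these up against the human
group means / choice counts measure by measure and flags where the
phase-1 -> phase-2 direction of change disagrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
import yaml

from .design import GROUPS, PAIRS, PHASES
from .model import CausalSupportModel, ModelConfig

__all__ = [
    "ScenarioPrediction",
    "HumanSummary",
    "ComparisonReport",
    "STRENGTH_GROUPS",
    "MEASURES",
    "run_all_scenarios",
    "predictions_frame",
    "code_structure_choice",
    "uncertainty_from_confidence",
    "load_human_summary",
    "ordinal_comparison",
    "plot_predictions",
]

# Which design group plays the "strong" / "weak" role for each target cause:
# the labels refer to the model-derived strength of that target at the end of
# phase 2.
STRENGTH_GROUPS: dict[str, dict[str, str]] = {
    "confounded_CD": {"strong": "C_strong_I_weak", "weak": "C_weak_I_strong"},
    "interacting_IJ": {"strong": "C_weak_I_strong", "weak": "C_strong_I_weak"},
}

MEASURES = ("structure", "strength", "uncertainty")

_CHOICE_CODES = {"produces": 1, "no_influence": -1, "cant_tell": 0}

_DIRECTION_DEADBAND = 1e-9


@dataclass(frozen=True)
class ScenarioPrediction:
    """Model quantities for one target cause x phase x group."""

    group: str
    pair: str
    phase: str
    support: float
    scaled_support: float
    strength_scaled: float
    entropy: float


def run_all_scenarios(
    config: Optional[ModelConfig] = None, cumulative: bool = True
) -> list[ScenarioPrediction]:
    """Fit the model in all eight scenarios (2 pairs x 2 groups x 2 phases).

    Phase-2 datasets pool both phases when ``cumulative`` is true, matching
    judgments made over all information seen so far.  The run is fully
    deterministic for a fixed configuration.
    """
    config = config or ModelConfig()
    predictions = []
    for pair in PAIRS:
        for group in GROUPS:
            for phase in PHASES:
                res = CausalSupportModel.from_design(
                    group, pair, phase, cumulative=cumulative, config=config
                ).fit()
                predictions.append(
                    ScenarioPrediction(
                        group=group,
                        pair=pair,
                        phase=phase,
                        support=res.support,
                        scaled_support=res.scaled_support,
                        strength_scaled=res.strength_scaled,
                        entropy=res.entropy,
                    )
                )
    return predictions


def predictions_frame(predictions: Iterable[ScenarioPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": p.group,
                "pair": p.pair,
                "phase": p.phase,
                "support": p.support,
                "scaled_support": p.scaled_support,
                "strength_scaled": p.strength_scaled,
                "entropy": p.entropy,
            }
            for p in predictions
        ]
    )


def code_structure_choice(choice: str) -> int:
    """Code a categorical structure choice: produces -> +1, no influence -> -1, can't tell -> 0."""
    try:
        return _CHOICE_CODES[choice]
    except KeyError:
        raise ValueError(
            f"unknown structure choice {choice!r}; valid choices are {sorted(_CHOICE_CODES)}"
        ) from None


def uncertainty_from_confidence(mean_confidence: float) -> float:
    """Flip a 0-100 confidence mean onto the uncertainty scale (100 - confidence)."""
    if not (0.0 <= mean_confidence <= 100.0):
        raise ValueError(f"mean confidence must lie in [0, 100], got {mean_confidence}")
    return 100.0 - mean_confidence


@dataclass(frozen=True)
class HumanSummary:
    """Published group-level human judgments: means, choice counts, coded directions.

    Per-participant ratings and some per-group choice splits were never
    published; those fields are ``None`` and only the ordinal direction of the
    coded structure judgment (derivable from the published counts) is stored.
    """

    means: dict
    structure_choices: dict
    structure_directions: dict

    def mean(self, pair: str, strength_label: str, measure: str, phase: str) -> float:
        return float(self.means[pair][strength_label][measure][phase])

    def group_size(self, pair: str, strength_label: str) -> int:
        return int(self.means[pair][strength_label]["n"])

    def direction(self, pair: str, strength_label: str, measure: str) -> str:
        """Phase-1 -> phase-2 direction ("increase"/"decrease") for one measure."""
        if measure == "structure":
            return self.structure_directions[pair][strength_label]
        v1 = self.mean(pair, strength_label, measure, "phase1")
        v2 = self.mean(pair, strength_label, measure, "phase2")
        return _direction(v1, v2)


def load_human_summary() -> HumanSummary:
    text = resources.files("causalsupport.data").joinpath("human_summary.yaml").read_text()
    raw = yaml.safe_load(text)
    return HumanSummary(
        means=raw["means"],
        structure_choices=raw["structure_choices"],
        structure_directions=raw["structure_directions"],
    )


def _direction(v1: float, v2: float) -> str:
    if v2 > v1 + _DIRECTION_DEADBAND:
        return "increase"
    if v2 < v1 - _DIRECTION_DEADBAND:
        return "decrease"
    return "flat"


@dataclass(frozen=True)
class ComparisonReport:
    """Per-measure phase-direction comparison between model and human judgments."""

    frame: pd.DataFrame

    @property
    def divergences(self) -> list[tuple[str, str, str]]:
        rows = self.frame[~self.frame["agree"]]
        return [tuple(r) for r in rows[["pair", "strength_label", "measure"]].itertuples(index=False)]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __str__(self) -> str:
        lines = ["Model vs. human phase-1 -> phase-2 directions", "-" * 72]
        for row in self.frame.itertuples(index=False):
            flag = "agree  " if row.agree else "DIVERGE"
            lines.append(
                f"{row.pair:15s} {row.strength_label:6s} {row.measure:12s} "
                f"model {row.model_direction:8s} human {row.human_direction:8s} [{flag}]"
            )
        return "\n".join(lines)


# Model quantity standing in for each judged measure.
_MODEL_MEASURE_FIELDS = {
    "structure": "support",
    "strength": "strength_scaled",
    "uncertainty": "entropy",
}


def ordinal_comparison(
    predictions: Iterable[ScenarioPrediction], human: HumanSummary
) -> ComparisonReport:
    """Compare phase-1 -> phase-2 directions of model predictions and human judgments.

    Causal support stands in for the coded structure judgment, scaled posterior
    mean for the strength rating, and posterior entropy for rated uncertainty
    (100 - confidence).  Rows where the directions differ are flagged.
    """
    index: dict[tuple[str, str, str], ScenarioPrediction] = {}
    for p in predictions:
        index[(p.pair, p.group, p.phase)] = p
    rows = []
    for pair in PAIRS:
        for strength_label, group in STRENGTH_GROUPS[pair].items():
            for phase in PHASES:
                if (pair, group, phase) not in index:
                    raise ValueError(
                        f"predictions do not cover scenario ({pair}, {group}, {phase})"
                    )
            p1 = index[(pair, group, "phase1")]
            p2 = index[(pair, group, "phase2")]
            for measure in MEASURES:
                field_name = _MODEL_MEASURE_FIELDS[measure]
                model_dir = _direction(getattr(p1, field_name), getattr(p2, field_name))
                human_dir = human.direction(pair, strength_label, measure)
                rows.append(
                    {
                        "pair": pair,
                        "strength_label": strength_label,
                        "group": group,
                        "measure": measure,
                        "model_phase1": getattr(p1, field_name),
                        "model_phase2": getattr(p2, field_name),
                        "model_direction": model_dir,
                        "human_direction": human_dir,
                        "agree": model_dir == human_dir,
                    }
                )
    return ComparisonReport(frame=pd.DataFrame(rows))


def plot_predictions(predictions: Iterable[ScenarioPrediction]):
    """Bar panels of model predictions per target cause: structure, strength, uncertainty."""
    import matplotlib.pyplot as plt

    frame = predictions_frame(predictions)
    fig, axes = plt.subplots(len(PAIRS), 3, figsize=(10, 6), squeeze=False)
    panels = [("scaled_support", "structure (scaled support)"), ("strength_scaled", "strength x100"), ("entropy", "entropy (nats)")]
    for i, pair in enumerate(PAIRS):
        sub = frame[frame["pair"] == pair]
        for j, (col, title) in enumerate(panels):
            ax = axes[i][j]
            labels, heights = [], []
            for strength_label, group in STRENGTH_GROUPS[pair].items():
                for phase in PHASES:
                    row = sub[(sub["group"] == group) & (sub["phase"] == phase)]
                    labels.append(f"{strength_label[0].upper()}{phase[-1]}")
                    heights.append(float(row[col].iloc[0]))
            ax.bar(range(len(heights)), heights)
            ax.set_xticks(range(len(labels)), labels)
            ax.set_title(f"{pair}: {title}", fontsize=9)
    fig.tight_layout()
    return fig
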