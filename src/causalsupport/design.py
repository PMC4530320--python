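"""The packaged two-group, two-phase experimental design.

Two pairs of candidate causes are trained within each participant group: a
*confounded* pair (C and D, which in phase 1 only ever occur together) and an
*interacting* pair (I and J, whose compound probability in phase 2 is
inconsistent with their elemental probabilities).  Every trial type that occurs
in a phase is presented 20 times; each group sees 200 trials in total.

The design is shipped as a YAML fixture and exposed as typed objects; helper
functions slice it into the contingency datasets the causal model consumes and
expand it into seeded trial sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .contingency import ContingencyDataset

__all__ = [
    "GROUPS",
    "PHASES",
    "TRIAL_TYPES",
    "PAIRS",
    "ExperimentDesign",
    "TrialSequence",
    "load_design",
    "extract_pair_dataset",
    "generate_trial_sequence",
]

GROUPS = ("C_strong_I_weak", "C_weak_I_strong")
PHASES = ("phase1", "phase2")
TRIAL_TYPES = ("CD", "C", "IJ", "I", "J", "NM")
PAIRS = ("confounded_CD", "interacting_IJ")

# Which trial types feed each target-cause analysis, and the (target, alternative)
# presence pattern each type corresponds to.  The alternative of the confounded
# pair (D) never occurs alone, so no (0, 1) cell exists for that pair.
_PAIR_CONFIGS: dict[str, dict[str, tuple[int, int]]] = {
    "confounded_CD": {"CD": (1, 1), "C": (1, 0), "NM": (0, 0)},
    "interacting_IJ": {"IJ": (1, 1), "I": (1, 0), "J": (0, 1), "NM": (0, 0)},
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Per-phase trial-type frequency tables for one group."""

    group: str
    phase_tables: dict[str, dict[str, tuple[int, int]]]

    @property
    def phase1(self) -> dict[str, tuple[int, int]]:
        return self.phase_tables["phase1"]

    @property
    def phase2(self) -> dict[str, tuple[int, int]]:
        return self.phase_tables["phase2"]

    @property
    def n_trials(self) -> int:
        return sum(ne + nn for table in self.phase_tables.values() for ne, nn in table.values())


def _validate_design(design: ExperimentDesign) -> None:
    for phase, table in design.phase_tables.items():
        for trial_type, (ne, nn) in table.items():
            total = ne + nn
            if total not in (0, 20):
                raise ValueError(
                    f"{design.group} {phase} {trial_type}: occurring trial types have "
                    f"exactly 20 trials, got {total}"
                )
    if design.n_trials != 200:
        raise ValueError(f"{design.group}: total trials must be 200, got {design.n_trials}")


def load_design(group: str) -> ExperimentDesign:
    """Load the packaged design for one group ("C_strong_I_weak" or "C_weak_I_strong")."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid groups are {list(GROUPS)}")
    text = resources.files("causalsupport.data").joinpath("design_table.yaml").read_text()
    raw = yaml.safe_load(text)["groups"][group]
    phase_tables = {
        phase: {t: (int(v[0]), int(v[1])) for t, v in raw[phase].items()} for phase in PHASES
    }
    design = ExperimentDesign(group=group, phase_tables=phase_tables)
    _validate_design(design)
    return design


def extract_pair_dataset(
    design: ExperimentDesign,
    pair: str,
    phase: str,
    cumulative: bool = False,
) -> ContingencyDataset:
    """Slice the design into the contingency dataset for one target cause.

    With ``cumulative=True`` and ``phase="phase2"`` the counts pool both phases,
    matching judgments elicited over all information seen so far; otherwise the
    counts are phase-specific.  Trial types with zero presentations contribute
    no cell.
    """
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}; valid pairs are {list(PAIRS)}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; valid phases are {list(PHASES)}")
    phases = ("phase1", "phase2") if (cumulative and phase == "phase2") else (phase,)
    counts: dict[tuple[int, int], tuple[int, int]] = {}
    for trial_type, config in _PAIR_CONFIGS[pair].items():
        ne = sum(design.phase_tables[p][trial_type][0] for p in phases)
        nn = sum(design.phase_tables[p][trial_type][1] for p in phases)
        if ne + nn > 0:
            counts[config] = (ne, nn)
    suffix = ", cumulative" if (cumulative and phase == "phase2") else ""
    label = f"{design.group}, {pair}, {phase}{suffix}"
    return ContingencyDataset.from_counts(counts, label=label)


@dataclass(frozen=True)
class TrialSequence:
    """A seeded random ordering of the trials of one phase."""

    trials: tuple[tuple[str, bool], ...]
    group: str
    phase: str
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def aggregate(self) -> dict[str, tuple[int, int]]:
        """Recover per-type (n_effect, n_no_effect) counts from the sequence."""
        agg: dict[str, list[int]] = {}
        for trial_type, effect in self.trials:
            counts = agg.setdefault(trial_type, [0, 0])
            counts[0 if effect else 1] += 1
        return {t: (c[0], c[1]) for t, c in agg.items()}


def generate_trial_sequence(design: ExperimentDesign, phase: str, seed: int) -> TrialSequence:
    """Expand one phase of the design into a seeded random permutation of trials."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; valid phases are {list(PHASES)}")
    trials: list[tuple[str, bool]] = []
    for trial_type in TRIAL_TYPES:
        ne, nn = design.phase_tables[phase][trial_type]
        trials.extend([(trial_type, True)] * ne)
        trials.extend([(trial_type, False)] * nn)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    shuffled = tuple(trials[i] for i in order)
    return TrialSequence(trials=shuffled, group=design.group, phase=phase, seed=seed)
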