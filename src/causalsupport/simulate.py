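"""Synthetic contingency data and simulated participants.

`simulate_dataset` draws effect counts from a known causal graph and strength
vector — either Bernoulli sampling (Binomial counts per configuration) or an
exact-frequency mode that reproduces the deterministic rounded frequencies the
packaged design itself uses (e.g. 16 of 20 at p = 0.8).  `recovery_experiment`
wraps simulate -> fit loops for parameter-recovery checks, and
`simulate_cohort` produces seeded participant-level ratings from a simple
response model layered on the fitted quantities (repository scaffolding for
testing, not a claim about human response generation).

All randomness flows through an explicit seed; the same seed always reproduces
the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .contingency import CauseConfig, ContingencyCell, ContingencyDataset
from .design import GROUPS, PAIRS, PHASES
from .model import (
    CausalSupportModel,
    Graph,
    GRAPHS_BY_NAME,
    ModelConfig,
    ParamVector,
    effect_probability,
)

__all__ = [
    "GenerativeSpec",
    "RecoveryReport",
    "ResponseConfig",
    "SimulatedParticipant",
    "simulate_dataset",
    "recovery_experiment",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GenerativeSpec:
    """Ground truth for data generation: graph, strengths, trials per configuration."""

    true_graph: Graph
    true_params: ParamVector
    trials_per_config: dict[CauseConfig, int]
    sampling: str = "bernoulli"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling not in ("bernoulli", "exact_frequency"):
            raise ValueError(
                f"sampling must be 'bernoulli' or 'exact_frequency', got {self.sampling!r}"
            )
        for config, n in self.trials_per_config.items():
            if n < 0:
                raise ValueError(f"negative trial count {n} for {config}")

    @classmethod
    def from_yaml(cls, path) -> "GenerativeSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        graph = GRAPHS_BY_NAME[raw["graph"]]
        params = ParamVector(**{k: float(v) for k, v in raw["params"].items()})
        trials = {}
        for key, n in raw["trials"].items():
            # keys like "c1a0": target present, alternative absent
            trials[CauseConfig(int(key[1]), int(key[3]))] = int(n)
        return cls(
            true_graph=graph,
            true_params=params,
            trials_per_config=trials,
            sampling=raw.get("sampling", "bernoulli"),
            seed=int(raw.get("seed", 0)),
        )


def _true_probability(config: CauseConfig, spec: GenerativeSpec) -> float:
    params = ParamVector(
        w_B=spec.true_params.w_B,
        w_C=spec.true_params.w_C if spec.true_graph.target_link else 0.0,
        w_A=spec.true_params.w_A if spec.true_graph.alternative_link else 0.0,
    )
    return effect_probability(config, params, "noisy_or")


def simulate_dataset(spec: GenerativeSpec, rng: Optional[np.random.Generator] = None) -> ContingencyDataset:
    """Generate a contingency dataset from the ground-truth graph and strengths.

    Bernoulli mode draws Binomial(n, p) effect counts per configuration;
    exact-frequency mode sets them to round-half-up(n * p), deterministically.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cells = []
    for config in sorted(spec.trials_per_config):
        n = spec.trials_per_config[config]
        if n == 0:
            continue
        p = _true_probability(config, spec)
        if spec.sampling == "exact_frequency":
            n_effect = int(np.floor(n * p + 0.5))
        else:
            n_effect = int(rng.binomial(n, p))
        cells.append(ContingencyCell(config, n_effect, n - n_effect))
    label = f"simulated from {spec.true_graph.name} ({spec.sampling}, seed {spec.seed})"
    return ContingencyDataset(cells=tuple(cells), label=label)


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate parameter-recovery performance over replicates."""

    frame: pd.DataFrame
    bias: float
    rmse: float
    sign_accuracy: float

    def summary(self) -> str:
        return (
            f"recovery over {len(self.frame)} replicates: "
            f"bias = {self.bias:+.4f}, RMSE = {self.rmse:.4f}, "
            f"support sign accuracy = {self.sign_accuracy:.2%}"
        )


def recovery_experiment(
    spec: GenerativeSpec,
    config: Optional[ModelConfig] = None,
    replicates: int = 20,
) -> RecoveryReport:
    """Simulate -> fit repeatedly and score recovery of the target strength.

    Per replicate: the posterior-mean error on w_C and whether the sign of
    causal support matches the ground truth (positive if the true graph has a
    target link, non-positive otherwise).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or ModelConfig()
    rng = np.random.default_rng(spec.seed)
    true_wc = spec.true_params.w_C if spec.true_graph.target_link else 0.0
    rows = []
    for rep in range(replicates):
        dataset = simulate_dataset(spec, rng=rng)
        res = CausalSupportModel(dataset, config=config).fit()
        if spec.true_graph.target_link:
            sign_ok = res.support > 0
        else:
            sign_ok = res.support <= 0
        rows.append(
            {
                "replicate": rep,
                "support": res.support,
                "sign_correct": bool(sign_ok),
                "posterior_mean": res.strength,
                "error": res.strength - true_wc,
            }
        )
    frame = pd.DataFrame(rows)
    return RecoveryReport(
        frame=frame,
        bias=float(frame["error"].mean()),
        rmse=float(np.sqrt(np.mean(frame["error"] ** 2))),
        sign_accuracy=float(frame["sign_correct"].mean()),
    )


@dataclass(frozen=True)
class ResponseConfig:
    """Response-model noise for simulated participants.

    In the noiseless limit (sd = 0, temperature -> 0) the simulated ratings
    equal the model predictions exactly and choices equal the argmax coding.
    """

    strength_noise_sd: float = 10.0
    confidence_noise_sd: float = 10.0
    temperature: float = 1.0


@dataclass(frozen=True)
class SimulatedParticipant:
    """One simulated participant: group assignment and per-scenario responses."""

    participant: int
    group: str
    responses: dict[tuple[str, str], dict]  # (pair, phase) -> {strength, confidence, choice}


def _choice_probabilities(scaled_support: float, temperature: float) -> np.ndarray:
    """Softmax over (produces, no_influence, cant_tell) driven by scaled support."""
    logits = np.array([scaled_support, -scaled_support, 0.0])
    if temperature <= 0:
        probs = np.zeros(3)
        probs[int(np.argmax(logits))] = 1.0
        return probs
    z = logits / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def simulate_cohort(
    n_participants: int,
    response_config: Optional[ResponseConfig] = None,
    model_config: Optional[ModelConfig] = None,
    cumulative: bool = True,
    seed: int = 0,
) -> list[SimulatedParticipant]:
    """Seeded cohort of simulated ratings and choices for every scenario.

    Participants alternate between the two design groups.  Strength ratings
    are 100 x posterior mean plus Gaussian noise; confidence is
    100 x (1 - exp(entropy)) plus noise (exp(entropy) is the uniform-relative
    concentration of the posterior, 1 for the uniform density); structure
    choices are drawn from a softmax over the coded options driven by scaled
    support.  All ratings are clipped to [0, 100].
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    from .pipeline import run_all_scenarios

    response_config = response_config or ResponseConfig()
    predictions = run_all_scenarios(config=model_config, cumulative=cumulative)
    index = {(p.group, p.pair, p.phase): p for p in predictions}
    rng = np.random.default_rng(seed)
    cohort = []
    choices = ("produces", "no_influence", "cant_tell")
    for i in range(n_participants):
        group = GROUPS[i % len(GROUPS)]
        responses = {}
        for pair in PAIRS:
            for phase in PHASES:
                pred = index[(group, pair, phase)]
                strength = pred.strength_scaled
                confidence = 100.0 * (1.0 - np.exp(pred.entropy))
                if response_config.strength_noise_sd > 0:
                    strength += rng.normal(0.0, response_config.strength_noise_sd)
                if response_config.confidence_noise_sd > 0:
                    confidence += rng.normal(0.0, response_config.confidence_noise_sd)
                probs = _choice_probabilities(pred.scaled_support, response_config.temperature)
                choice = choices[int(rng.choice(3, p=probs))]
                responses[(pair, phase)] = {
                    "strength": float(np.clip(strength, 0.0, 100.0)),
                    "confidence": float(np.clip(confidence, 0.0, 100.0)),
                    "choice": choice,
                }
        cohort.append(SimulatedParticipant(participant=i, group=group, responses=responses))
    return cohort
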