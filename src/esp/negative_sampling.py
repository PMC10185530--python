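"""Similarity-windowed, frequency-matched sampling of negative pairs.

For every positive enzyme-substrate pair, the sampler draws ``n_per_positive``
molecules (default 3) uniformly at random from the pool, restricted to a
Tanimoto window around the true substrate (default 0.7-0.95) so the
negatives are hard: similar to real substrates but presumed non-binding.
If the window holds too few candidates the lower bound is relaxed downward
in fixed steps (default 0.2). Each molecule may appear among the negatives
at most ``cap_factor`` times its occurrence count among the positives
(default 3x), which matches the negative molecule frequency distribution to
the positive one.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

from esp.data_io import PairRecord
from esp.molecule_features import SimilarityMatrix

__all__ = ["SamplingConfig", "SamplingReport", "sample_negatives", "occurrence_counts"]


@dataclass
class SamplingConfig:
    n_per_positive: int = 3
    upper_bound: float = 0.95
    lower_bound: float = 0.7
    relaxation_step: float = 0.2
    cap_factor: int = 3
    seed: int = 0
    #: exclude molecules that are known substrates of the same enzyme
    exclude_known_substrates: bool = True
    #: what to do when even the fully relaxed window is exhausted by the cap:
    #: "lift_cap" (default) lifts the cap for that positive and flags the event,
    #: guaranteeing the full 3:1 ratio; "shortfall" emits fewer negatives instead
    on_exhaustion: str = "lift_cap"

    def __post_init__(self) -> None:
        if not (0 <= self.lower_bound < self.upper_bound <= 1):
            raise ValueError("need 0 <= lower_bound < upper_bound <= 1")
        if self.n_per_positive < 1:
            raise ValueError("n_per_positive must be >= 1")
        if self.relaxation_step <= 0:
            raise ValueError("relaxation_step must be > 0")
        if self.on_exhaustion not in ("shortfall", "lift_cap"):
            raise ValueError("on_exhaustion must be 'shortfall' or 'lift_cap'")


@dataclass
class SamplingReport:
    n_positives: int = 0
    n_negatives: int = 0
    n_relaxed: int = 0  # positives that needed a lowered bound
    n_shortfall: int = 0  # positives with fewer than n_per_positive negatives
    n_cap_lifted: int = 0
    effective_lower_bound: dict[int, float] = field(default_factory=dict)
    sampled_counts: dict[str, int] = field(default_factory=dict)


def occurrence_counts(positives: list[PairRecord]) -> dict[str, int]:
    """How often each molecule occurs as a substrate among the positive pairs."""
    return dict(collections.Counter(p.molecule_id for p in positives if p.label == 1))


def sample_negatives(positives: list[PairRecord], sim: SimilarityMatrix,
                     config: SamplingConfig | None = None
                     ) -> tuple[list[PairRecord], SamplingReport]:
    """Generate sampled negative pairs for a set of positives.

    Positives are processed in seeded random order so cap consumption does
    not systematically favour early enzymes. Emitted pairs carry label 0 and
    evidence "sampled"; a pair (enzyme, molecule) is never emitted twice and
    never contradicts a positive of the same enzyme (configurable).
    """
    config = config or SamplingConfig()
    if any(p.label != 1 for p in positives):
        raise ValueError("sample_negatives expects positives only (label 1)")
    report = SamplingReport(n_positives=len(positives))
    if not positives:
        return [], report

    missing = sorted({p.molecule_id for p in positives} - set(sim.ids))
    if missing:
        raise ValueError(f"positive molecules absent from similarity matrix: {missing}")

    rng = np.random.default_rng(config.seed)
    occurrence = occurrence_counts(positives)
    ceiling = {m: config.cap_factor * c for m, c in occurrence.items()}
    sampled = collections.Counter()
    substrates_of: dict[str, set[str]] = collections.defaultdict(set)
    for p in positives:
        substrates_of[p.enzyme_id].add(p.molecule_id)

    all_ids = np.array(sim.ids)
    emitted: set[tuple[str, str]] = set()
    negatives: list[PairRecord] = []

    order = rng.permutation(len(positives))
    for rank, idx in enumerate(order):
        pos = positives[int(idx)]
        row = sim.row(pos.molecule_id)
        forbidden = substrates_of[pos.enzyme_id] if config.exclude_known_substrates \
            else {pos.molecule_id}

        def candidates(lower: float, respect_cap: bool = True) -> list[str]:
            in_window = (row >= lower) & (row <= config.upper_bound)
            cands = []
            for m in all_ids[in_window]:
                if m in forbidden or (pos.enzyme_id, m) in emitted:
                    continue
                # a molecule never seen among positives has ceiling 0: the
                # frequency-matching rule only admits molecules in proportion
                # to their positive occurrence
                if respect_cap and sampled[m] >= ceiling.get(m, 0):
                    continue
                cands.append(m)
            return cands

        lower = config.lower_bound
        chosen: list[str] = []
        relaxed = False
        while True:
            pool = [m for m in candidates(lower) if m not in chosen]
            need = config.n_per_positive - len(chosen)
            if len(pool) >= need:
                pick = rng.choice(len(pool), size=need, replace=False)
                chosen.extend(pool[i] for i in sorted(pick))
                break
            chosen.extend(pool)
            if lower <= 0:
                break
            lower = max(0.0, lower - config.relaxation_step)
            relaxed = True

        if len(chosen) < config.n_per_positive and config.on_exhaustion == "lift_cap":
            pool = [m for m in candidates(0.0, respect_cap=False) if m not in chosen]
            need = config.n_per_positive - len(chosen)
            if pool:
                pick = rng.choice(len(pool), size=min(need, len(pool)), replace=False)
                chosen.extend(pool[i] for i in sorted(pick))
                report.n_cap_lifted += 1

        if relaxed:
            report.n_relaxed += 1
        report.effective_lower_bound[int(idx)] = lower
        if len(chosen) < config.n_per_positive:
            report.n_shortfall += 1
        for m in chosen:
            sampled[m] += 1
            emitted.add((pos.enzyme_id, m))
            negatives.append(
                PairRecord(pos.enzyme_id, m, label=0, evidence="sampled",
                           origin=f"sampled_for:{pos.molecule_id}")
            )

    report.n_negatives = len(negatives)
    report.sampled_counts = dict(sampled)
    return negatives, report
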