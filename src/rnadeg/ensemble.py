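"""Combining prediction sets: weighted averaging and genetic-algorithm
subset selection.

The genetic algorithm searches over (subset, weights) chromosomes — at most
``max_members`` of the candidate models, with simplex-normalized non-negative
weights — minimizing MCRMSE on an optimization split.  The initial population
seeds every single-candidate ensemble and elitism preserves the incumbent, so
the returned ensemble never scores worse than the best single candidate on
the optimization split.  Held-out evaluation is kept separate from the
optimization score so that optimisation-split overfitting stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .evaluation import mcrmse
from .records import PredictionSet, RnaRecord


@dataclass
class EnsembleSpec:
    """Selected members, their weights and the optimization-split score."""

    member_ids: list[str]
    weights: np.ndarray
    objective_score: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.member_ids):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / s

    def to_dict(self) -> dict:
        return {
            "member_ids": list(self.member_ids),
            "weights": self.weights.tolist(),
            "objective_score": float(self.objective_score),
        }


def average_predictions(members: Sequence[PredictionSet],
                        weights: Sequence[float] | None = None) -> PredictionSet:
    """Per-position weighted mean of aligned prediction sets."""
    if not members:
        raise ValueError("no prediction sets to average")
    first = members[0]
    for m in members[1:]:
        if not first.aligned_with(m):
            raise ValueError("prediction sets are not aligned (ids/channels/lengths)")
    if weights is None:
        w = np.full(len(members), 1.0 / len(members))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(members),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    out: dict[str, dict[str, np.ndarray]] = {}
    for rid in first.ids:
        out[rid] = {}
        for channel, arr in first[rid].items():
            acc = w[0] * arr.copy()
            for wi, m in zip(w[1:], members[1:]):
                acc = acc + wi * m[rid][channel]
            out[rid][channel] = acc
    return PredictionSet(out)


class _Objective:
    """Stacks candidates and truth into per-channel matrices so that fitness
    of a weight vector is a few matrix products."""

    def __init__(self, candidates: Mapping[str, PredictionSet],
                 records: Sequence[RnaRecord],
                 channels: Sequence[str] | None = None):
        self.names = list(candidates)
        sets = [candidates[n] for n in self.names]
        first = sets[0]
        for s in sets[1:]:
            if not first.aligned_with(s):
                raise ValueError("candidate prediction sets are not aligned")
        # the optimization split is defined by `records`; candidate ids not
        # listed there (e.g. a held-out split) are simply not scored
        if channels is None:
            channels = first.channels
        self.channels = list(channels)
        self.preds: dict[str, np.ndarray] = {}
        self.truth: dict[str, np.ndarray] = {}
        for channel in self.channels:
            rows, t = [], []
            for rec in records:
                rid = rec.id
                if rid not in first:
                    raise KeyError(f"no candidate predictions for record {rid}")
                if channel not in rec.values:
                    raise KeyError(f"no truth for id {rid} channel {channel}")
                n = rec.seq_scored
                rows.append(np.stack([s[rid][channel][:n] for s in sets]))
                t.append(rec.values[channel])
            self.preds[channel] = np.concatenate(rows, axis=1)
            self.truth[channel] = np.concatenate(t)

    def __call__(self, weights: np.ndarray) -> float:
        rmses = []
        for channel in self.channels:
            y = weights @ self.preds[channel]
            rmses.append(np.sqrt(np.mean((y - self.truth[channel]) ** 2)))
        return float(np.mean(rmses))


def evaluate_ensemble(spec: EnsembleSpec, candidates: Mapping[str, PredictionSet],
                      records: Sequence[RnaRecord],
                      channels: Sequence[str] | None = None) -> float:
    """MCRMSE of an ensemble spec on an evaluation split (kept distinct from
    the optimization score stored in the spec)."""
    avg = average_predictions([candidates[n] for n in spec.member_ids], spec.weights)
    if channels is None:
        channels = avg.channels
    meas = {c: [r.values[c] for r in records] for c in channels}
    hats = {c: [avg[r.id][c][: r.seq_scored] for r in records] for c in channels}
    return mcrmse(meas, hats).mcrmse


def _tie_key(mask: np.ndarray, names: list[str]):
    members = tuple(sorted(n for n, on in zip(names, mask) if on))
    return (int(mask.sum()), members)


def ga_select(candidates: Mapping[str, PredictionSet],
              records: Sequence[RnaRecord],
              channels: Sequence[str] | None = None,
              max_members: int = 10,
              generations: int = 200,
              pop_size: int = 64,
              mutation_rate: float = 0.05,
              elitism: int = 2,
              uniform_weights: bool = False,
              seed: int | None = None) -> EnsembleSpec:
    """Genetic-algorithm selection of at most ``max_members`` candidates.

    Chromosomes carry an active-member mask and continuous weights
    (renormalized over the active members; set ``uniform_weights`` for
    equal weighting of the selected subset).  Seeded and reproducible; ties
    are broken by fewer members, then lexical member ids.
    """
    if not candidates:
        raise ValueError("no candidate prediction sets")
    rng = np.random.default_rng(seed)
    objective = _Objective(candidates, records, channels)
    names = objective.names
    n = len(names)
    max_members = min(max_members, n)

    def full_weights(mask: np.ndarray, w: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        active = np.flatnonzero(mask)
        if uniform_weights:
            out[active] = 1.0 / len(active)
        else:
            wa = w[active]
            if wa.sum() <= 0:
                wa = np.ones(len(active))
            out[active] = wa / wa.sum()
        return out

    def repair(mask: np.ndarray) -> np.ndarray:
        active = np.flatnonzero(mask)
        if len(active) == 0:
            mask = mask.copy()
            mask[rng.integers(n)] = True
        elif len(active) > max_members:
            mask = mask.copy()
            drop = rng.choice(active, size=len(active) - max_members, replace=False)
            mask[drop] = False
        return mask

    def fitness(mask: np.ndarray, w: np.ndarray) -> float:
        return objective(full_weights(mask, w))

    # population: seed all singletons, then random subsets
    population: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(min(n, pop_size)):
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        population.append((mask, np.ones(n)))
    while len(population) < pop_size:
        size = int(rng.integers(1, max_members + 1))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=size, replace=False)] = True
        population.append((mask, rng.random(n) + 1e-3))

    scores = np.array([fitness(m, w) for m, w in population])
    best_single = scores[: min(n, pop_size)].min()

    def best_index() -> int:
        order = sorted(
            range(len(population)),
            key=lambda i: (scores[i], _tie_key(population[i][0], names)),
        )
        return order[0]

    for _ in range(generations):
        order = sorted(
            range(len(population)),
            key=lambda i: (scores[i], _tie_key(population[i][0], names)),
        )
        new_pop = [population[i] for i in order[:elitism]]
        new_scores = [scores[i] for i in order[:elitism]]
        while len(new_pop) < pop_size:
            # tournament selection, size 3
            def pick():
                idx = rng.integers(len(population), size=3)
                return population[min(idx, key=lambda i: scores[i])]

            (m1, w1), (m2, w2) = pick(), pick()
            cross = rng.random(n) < 0.5
            mask = np.where(cross, m1, m2)
            w = np.where(cross, w1, w2)
            flip = rng.random(n) < mutation_rate
            mask = mask ^ flip
            w = w * np.exp(0.3 * rng.standard_normal(n) * (rng.random(n) < mutation_rate))
            w = np.abs(w) + 1e-9
            mask = repair(np.asarray(mask, dtype=bool))
            new_pop.append((mask, w))
            new_scores.append(fitness(mask, w))
        population, scores = new_pop, np.array(new_scores)
        # elitism invariant: never worse than the best single candidate
        assert scores.min() <= best_single + 1e-12

    i = best_index()
    mask, w = population[i]
    fw = full_weights(mask, w)
    active = np.flatnonzero(mask)
    member_ids = [names[j] for j in active]
    order = np.argsort(member_ids)
    return EnsembleSpec(
        member_ids=[member_ids[j] for j in order],
        weights=fw[active][order],
        objective_score=float(scores[i]),
    )
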