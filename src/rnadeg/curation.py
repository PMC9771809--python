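"""Dataset curation: signal-to-noise filtering and cluster-based splits.

Constructs pass the quality filter when every value across the degradation
channels lies strictly inside (min_value, max_value) and the SHAPE-reactivity
signal-to-noise ratio strictly exceeds a threshold.  Failing records are kept
and flagged (``SN_filter = 0``) rather than dropped.

For blind-test curation, sequences are clustered by agglomerative linkage on
pairwise normalized edit distance and the dendrogram is cut at a fixed
cophenetic height; every member of a cluster of size one, two or three goes
to the private test set, which is then topped up with one member from each of
a random selection of larger clusters, and the remainder is randomly
partitioned into training and public-test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .evaluation import record_sn_ratio
from .records import DEG_CHANNELS, RnaRecord

SPLITS = ("train", "public_test", "private_test")


@dataclass(frozen=True)
class FilterPolicy:
    """Quality-filter thresholds.  All comparisons are strict."""

    min_value_threshold: float = 0.5
    max_value_threshold: float = 20.0
    sn_threshold: float = 1.0
    channels_for_minmax: tuple[str, ...] | None = None  # None: deg channels present
    channel_for_sn: str = "reactivity"


def evaluate_policy(record: RnaRecord, policy: FilterPolicy | None = None) -> int:
    """Apply the filter to one record; returns the flag (1 pass, 0 fail)."""
    policy = policy or FilterPolicy()
    channels = policy.channels_for_minmax
    if channels is None:
        channels = tuple(c for c in DEG_CHANNELS if c in record.values)
    for c in channels:
        if c not in record.values:
            raise KeyError(f"record {record.id} lacks channel {c!r}")
    if policy.channel_for_sn not in record.values or policy.channel_for_sn not in record.errors:
        raise KeyError(
            f"record {record.id} lacks values/errors for SN channel "
            f"{policy.channel_for_sn!r}"
        )
    for c in channels:
        v = record.values[c]
        if v.size and not (v.min() > policy.min_value_threshold
                           and v.max() < policy.max_value_threshold):
            return 0
    sn = record_sn_ratio(record, channels=[policy.channel_for_sn], on_zero="exclude")
    return int(sn > policy.sn_threshold)


def apply_sn_filter(records: Sequence[RnaRecord],
                    policy: FilterPolicy | None = None) -> list[RnaRecord]:
    """Set ``SN_filter`` and ``signal_to_noise`` on every record (in place)
    and return the list.  Records are retained regardless of the flag."""
    policy = policy or FilterPolicy()
    for rec in records:
        rec.SN_filter = evaluate_policy(rec, policy)
        rec.signal_to_noise = record_sn_ratio(
            rec, channels=[policy.channel_for_sn], on_zero="exclude"
        )
    return list(records)


def _levenshtein(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b), 1)


def _hamming(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b)) / max(len(a), 1)


_METRICS = {"levenshtein": _levenshtein, "hamming": _hamming}


def pairwise_distances(sequences: Sequence[str], metric: str = "levenshtein") -> np.ndarray:
    """Condensed pairwise normalized distance vector (scipy pdist layout)."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    n = len(sequences)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = fn(sequences[i], sequences[j])
            k += 1
    return out


def cluster_sequences(sequences: Sequence[str], linkage_method: str = "ward",
                      cut: float = 0.5, metric: str = "levenshtein"
                      ) -> tuple[np.ndarray, dict[int, int]]:
    """Agglomerative clustering of sequences cut at a cophenetic height.

    Ward linkage on a precomputed, non-Euclidean distance is formally
    improper but is applied as commonly implemented; ``linkage_method`` may
    be set to "average" or "complete" instead.  Returns integer labels
    (1-based, aligned to input order) and per-cluster sizes.  Deterministic
    given the input order.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to cluster")
    if len(sequences) == 1:
        return np.array([1]), {1: 1}
    d = pairwise_distances(sequences, metric=metric)
    z = hierarchy.linkage(d, method=linkage_method)
    labels = hierarchy.fcluster(z, t=cut, criterion="distance")
    sizes = dict(zip(*np.unique(labels, return_counts=True)))
    return labels, {int(k): int(v) for k, v in sizes.items()}


@dataclass
class SplitAssignment:
    """Construct id -> split, with the cluster bookkeeping behind it."""

    cluster_label: dict[str, int]
    cluster_size: dict[str, int]
    split: dict[str, str] = field(default_factory=dict)

    def ids_in(self, which: str) -> list[str]:
        return [rid for rid, s in self.split.items() if s == which]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": rid,
                "cluster": self.cluster_label[rid],
                "cluster_size": self.cluster_size[rid],
                "split": self.split[rid],
            }
            for rid in self.split
        ]
        return pd.DataFrame(rows)


def assign_splits(labels: Mapping[str, int],
                  target_counts: Mapping[str, int],
                  seed: int | np.random.Generator | None = None) -> SplitAssignment:
    """Partition ids into train / public_test / private_test.

    Every member of a cluster of size <= 3 is assigned to the private test
    set.  If ``target_counts["private_test"]`` exceeds that, one randomly
    chosen member from each of a random selection of larger clusters is added
    until the target is met.  The remaining ids are shuffled and split into
    public_test (``target_counts["public_test"]``) and train (the rest, or
    ``target_counts["train"]`` if given, which must then match).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = sorted(labels)
    cluster_members: dict[int, list[str]] = {}
    for rid in ids:
        cluster_members.setdefault(labels[rid], []).append(rid)
    sizes = {rid: len(cluster_members[labels[rid]]) for rid in ids}

    private: list[str] = [rid for rid in ids if sizes[rid] <= 3]
    large_clusters = sorted(c for c, members in cluster_members.items() if len(members) > 3)

    target_private = int(target_counts.get("private_test", len(private)))
    if target_private < len(private):
        raise ValueError(
            f"private_test target {target_private} below the {len(private)} ids "
            "forced in by clusters of size <= 3"
        )
    max_private = len(private) + len(large_clusters)
    if target_private > max_private:
        raise ValueError(
            f"private_test target {target_private} infeasible: at most "
            f"{max_private} achievable (small-cluster members plus one per "
            "larger cluster)"
        )
    n_topup = target_private - len(private)
    chosen = rng.choice(len(large_clusters), size=n_topup, replace=False) if n_topup else []
    for idx in np.sort(np.asarray(chosen, dtype=int)):
        members = cluster_members[large_clusters[idx]]
        private.append(members[int(rng.integers(len(members)))])

    private_set = set(private)
    remaining = [rid for rid in ids if rid not in private_set]
    target_public = int(target_counts.get("public_test", 0))
    if target_public > len(remaining):
        raise ValueError(
            f"public_test target {target_public} infeasible: only "
            f"{len(remaining)} ids remain after private-test curation"
        )
    if "train" in target_counts:
        want_train = int(target_counts["train"])
        if want_train != len(remaining) - target_public:
            raise ValueError(
                f"train target {want_train} inconsistent: "
                f"{len(remaining) - target_public} ids remain"
            )
    perm = rng.permutation(len(remaining))
    public = {remaining[i] for i in perm[:target_public]}

    split = {}
    for rid in ids:
        if rid in private_set:
            split[rid] = "private_test"
        elif rid in public:
            split[rid] = "public_test"
        else:
            split[rid] = "train"
    return SplitAssignment(cluster_label=dict(labels), cluster_size=sizes, split=split)


def rescaling_diagnostic(records_a: Sequence[RnaRecord],
                         records_b: Sequence[RnaRecord],
                         channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Compare per-nucleotide-type medians between two measurement rounds.

    Reports, per channel and nucleotide type, the median of each round and
    whether round B's median falls inside round A's interquartile range.
    Diagnostic only: no rescaling is applied.
    """
    if channels is None:
        channels = sorted({c for r in records_a for c in r.values}
                          & {c for r in records_b for c in r.values})
    rows = []
    for channel in channels:
        for nt in "ACGU":
            pools = []
            for recs in (records_a, records_b):
                vals = [
                    r.values[channel][i]
                    for r in recs
                    if channel in r.values
                    for i in range(r.seq_scored)
                    if r.sequence[i] == nt
                ]
                pools.append(np.asarray(vals, dtype=float))
            a, b = pools
            if a.size == 0 or b.size == 0:
                continue
            q1, q3 = np.percentile(a, [25, 75])
            rows.append({
                "channel": channel,
                "nucleotide": nt,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "iqr_a_low": float(q1),
                "iqr_a_high": float(q3),
                "b_within_a_iqr": bool(q1 <= np.median(b) <= q3),
            })
    return pd.DataFrame(rows)
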