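"""Scoring metrics for per-nucleotide predictions.

The headline metric is the mean column RMSE (MCRMSE): positions are pooled
across constructs within each measurement channel, a root-mean-square error
is taken per channel, and the channel RMSEs are averaged,

    MCRMSE = (1/N_t) * sum_j sqrt( (1/n) * sum_i (y_ij - yhat_ij)^2 ).

Also provided: the per-construct signal-to-noise ratio (mean over channels of
the mean mu/sigma over positions), the fraction of predictions lying strictly
within the experimental error bar of the measurement (for Gaussian errors a
perfect predictor attains erf(1/sqrt(2)) ~ 68.3%), aggregation of
per-position signal over secondary-structure motifs, and Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import structure as st
from .records import PredictionSet, RnaRecord


@dataclass
class ScoreReport:
    """Per-channel RMSEs, their mean, and bookkeeping counts."""

    per_channel_rmse: dict[str, float]
    mcrmse: float
    n_scored_nt: dict[str, int]
    within_error_fraction: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_channel_rmse": self.per_channel_rmse,
            "mcrmse": self.mcrmse,
            "n_scored_nt": self.n_scored_nt,
            "within_error_fraction": self.within_error_fraction,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": c,
                "rmse": r,
                "n_scored_nt": self.n_scored_nt.get(c, 0),
                "within_error_fraction": self.within_error_fraction.get(c, np.nan),
            }
            for c, r in self.per_channel_rmse.items()
        ]
        return pd.DataFrame(rows)


def _pool(arrays) -> np.ndarray:
    if isinstance(arrays, np.ndarray) and arrays.ndim == 1:
        return arrays.astype(float)
    if isinstance(arrays, (list, tuple)):
        if arrays and np.isscalar(arrays[0]):
            return np.asarray(arrays, dtype=float)
        return np.concatenate([np.asarray(a, dtype=float).ravel() for a in arrays])
    return np.asarray(arrays, dtype=float).ravel()


def mcrmse(measured: Mapping[str, object], predicted: Mapping[str, object],
           mask: Mapping[str, object] | None = None,
           nan_policy: str = "raise") -> ScoreReport:
    """Mean column RMSE over channels, pooling positions across constructs.

    ``measured`` and ``predicted`` map channel -> 1-D array or list of arrays
    (one per construct); an optional boolean ``mask`` with the same layout
    restricts scoring to flagged positions.
    """
    if set(measured) != set(predicted):
        raise ValueError(
            f"channel mismatch: {sorted(measured)} vs {sorted(predicted)}"
        )
    per_channel: dict[str, float] = {}
    counts: dict[str, int] = {}
    for channel in measured:
        y = _pool(measured[channel])
        yhat = _pool(predicted[channel])
        if y.shape != yhat.shape:
            raise ValueError(f"channel {channel}: shape mismatch {y.shape} vs {yhat.shape}")
        keep = np.ones(len(y), dtype=bool)
        if mask is not None and channel in mask:
            keep = _pool(mask[channel]).astype(bool)
            if keep.shape != y.shape:
                raise ValueError(f"channel {channel}: mask shape mismatch")
        y, yhat = y[keep], yhat[keep]
        if y.size == 0:
            raise ValueError(f"channel {channel}: no scored positions")
        bad = ~(np.isfinite(y) & np.isfinite(yhat))
        if bad.any():
            if nan_policy == "omit":
                y, yhat = y[~bad], yhat[~bad]
                if y.size == 0:
                    raise ValueError(f"channel {channel}: all positions non-finite")
            else:
                raise ValueError(
                    f"channel {channel}: non-finite values at {int(bad.sum())} positions"
                )
        per_channel[channel] = float(np.sqrt(np.mean((y - yhat) ** 2)))
        counts[channel] = int(y.size)
    return ScoreReport(
        per_channel_rmse=per_channel,
        mcrmse=float(np.mean(list(per_channel.values()))),
        n_scored_nt=counts,
    )


def score_predictions(records: Sequence[RnaRecord], pred: PredictionSet,
                      channels: Sequence[str] | None = None,
                      nan_policy: str = "raise") -> ScoreReport:
    """Score a prediction set against measured records over scored positions.

    Adds the within-experimental-error fraction per channel when the records
    carry error arrays.
    """
    by_id = {r.id: r for r in records}
    missing = [rid for rid in pred.ids if rid not in by_id]
    if missing:
        raise KeyError(f"predictions for unknown record ids: {missing[:5]}")
    if channels is None:
        channels = [c for c in pred.channels]
    meas: dict[str, list] = {c: [] for c in channels}
    hats: dict[str, list] = {c: [] for c in channels}
    errs: dict[str, list] = {c: [] for c in channels}
    have_err = {c: True for c in channels}
    for rid in pred.ids:
        rec = by_id[rid]
        for c in channels:
            if c not in pred[rid]:
                raise KeyError(f"record {rid}: no prediction for channel {c}")
            if c not in rec.values:
                raise KeyError(f"record {rid}: no measurement for channel {c}")
            yhat = pred[rid][c][: rec.seq_scored]
            if len(yhat) < rec.seq_scored:
                raise ValueError(
                    f"record {rid}: prediction for {c} covers {len(yhat)} of "
                    f"{rec.seq_scored} scored positions"
                )
            meas[c].append(rec.values[c])
            hats[c].append(yhat)
            if c in rec.errors:
                errs[c].append(rec.errors[c])
            else:
                have_err[c] = False
    report = mcrmse(meas, hats, nan_policy=nan_policy)
    for c in channels:
        if have_err[c]:
            report.within_error_fraction[c] = within_error_fraction(
                _pool(hats[c]), _pool(meas[c]), _pool(errs[c])
            )
    return report


def sn_ratio(mu, sigma, on_zero: str = "raise") -> float:
    """Signal-to-noise: mean over channels of the per-channel mean of
    mu/sigma over positions.

    ``mu`` and ``sigma`` are (channels x positions) arrays or lists of
    per-channel 1-D arrays.  ``on_zero`` controls positions with sigma = 0:
    "raise" (default) or "exclude".
    """
    mus = [np.asarray(m, dtype=float).ravel() for m in np.atleast_2d(mu)] \
        if isinstance(mu, np.ndarray) else [np.asarray(m, dtype=float).ravel() for m in mu]
    sigmas = [np.asarray(s, dtype=float).ravel() for s in np.atleast_2d(sigma)] \
        if isinstance(sigma, np.ndarray) else [np.asarray(s, dtype=float).ravel() for s in sigma]
    if len(mus) != len(sigmas):
        raise ValueError("mu and sigma must have the same number of channels")
    channel_means = []
    for m, s in zip(mus, sigmas):
        if m.shape != s.shape:
            raise ValueError("mu and sigma must align position-wise")
        zero = s == 0
        if zero.any():
            if on_zero == "exclude":
                m, s = m[~zero], s[~zero]
                if m.size == 0:
                    raise ValueError("all positions excluded (sigma = 0)")
            else:
                raise ValueError(
                    f"sigma = 0 at {int(zero.sum())} positions; "
                    "use on_zero='exclude' to drop them"
                )
        channel_means.append(np.mean(m / s))
    return float(np.mean(channel_means))


def record_sn_ratio(record: RnaRecord, channels: Sequence[str] | None = None,
                    on_zero: str = "raise") -> float:
    """Signal-to-noise of one record over the given channels (default: all
    channels that carry both values and errors)."""
    if channels is None:
        channels = [c for c in record.values if c in record.errors]
    if not channels:
        raise ValueError(f"record {record.id}: no channels with value and error arrays")
    mu = [record.values[c] for c in channels]
    sigma = [record.errors[c] for c in channels]
    return sn_ratio(mu, sigma, on_zero=on_zero)


def within_error_fraction(predicted, measured, error) -> float:
    """Fraction of positions with |predicted - measured| strictly below the
    experimental error bar."""
    p = np.asarray(predicted, dtype=float).ravel()
    m = np.asarray(measured, dtype=float).ravel()
    e = np.asarray(error, dtype=float).ravel()
    if not (p.shape == m.shape == e.shape):
        raise ValueError(f"length mismatch: {p.shape}, {m.shape}, {e.shape}")
    if np.any(e < 0):
        raise ValueError("error bars must be non-negative")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(p - m) < e))


#: Default motif bins: the seven loop classes plus derived motifs.
DEFAULT_MOTIFS = ("S", "H", "I", "B", "M", "X", "E",
                  "triloop", "symmetric_internal", "asymmetric_internal")


def motif_positions(pt: st.PairTable, triloop_length: int = 3) -> dict[str, list[int]]:
    """Positions belonging to each motif bin of one structure.

    Derived bins: ``triloop`` (hairpin loop of exactly ``triloop_length``
    unpaired nt), ``symmetric_internal`` / ``asymmetric_internal`` (internal
    loops split by equality of their two side lengths).  Derived bins overlap
    the base loop-class bins.
    """
    bins: dict[str, list[int]] = {m: [] for m in DEFAULT_MOTIFS}
    bins["S"] = [i for i in range(len(pt)) if pt.is_paired(i)]
    for seg in st.loop_segments(pt):
        bins[seg.kind].extend(seg.positions)
        if seg.kind == "H" and len(seg.positions) == triloop_length:
            bins["triloop"].extend(seg.positions)
        if seg.kind == "I":
            key = "symmetric_internal" if seg.sides[0] == seg.sides[1] else "asymmetric_internal"
            bins[key].extend(seg.positions)
    return bins


def motif_aggregate(values: Mapping[str, object],
                    structures: Mapping[str, object],
                    motifs: Sequence[str] = DEFAULT_MOTIFS,
                    triloop_length: int = 3) -> pd.DataFrame:
    """Pool per-position signal by structure motif across constructs.

    ``values`` maps construct id -> per-position array (may cover only a
    scored prefix of the structure); ``structures`` maps id -> dot-bracket
    string or :class:`~rnadeg.structure.PairTable`.  Returns a table indexed
    by motif with mean, sd and n of the pooled values.
    """
    unknown = set(motifs) - set(DEFAULT_MOTIFS)
    if unknown:
        raise ValueError(f"unknown motif bins: {sorted(unknown)}")
    pooled: dict[str, list[float]] = {m: [] for m in motifs}
    for rid, vals in values.items():
        if rid not in structures:
            raise KeyError(f"no structure for id {rid}")
        struct = structures[rid]
        pt = struct if isinstance(struct, st.PairTable) else st.parse_dotbracket(struct)
        arr = np.asarray(vals, dtype=float)
        bins = motif_positions(pt, triloop_length=triloop_length)
        for m in motifs:
            for pos in bins[m]:
                if pos < len(arr):
                    pooled[m].append(arr[pos])
    rows = []
    for m in motifs:
        v = np.asarray(pooled[m], dtype=float)
        rows.append({
            "motif": m,
            "mean": float(v.mean()) if v.size else np.nan,
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            "n": int(v.size),
        })
    return pd.DataFrame(rows).set_index("motif")


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
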