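"""Windowed sequence+structure degradation models (the DegScore family).

The per-nucleotide degradation score at position *i* is modelled as a linear
function of one-hot sequence and loop-type indicators in a window of
half-width ``w`` around *i*:

    Y_i = sum_{k=-w..w} sum_{n in {A,C,G,U}} beta_{k,n} I(seq[i+k] = n)
        + sum_{k=-w..w} sum_{s in {H,E,I,M,B,S}} beta_{k,s} I(loop[i+k] = s)
        + beta_0

giving (2w+1) * 10 + 1 free parameters (251 for the historical w = 12).
Offsets falling outside the sequence contribute all-zero indicator blocks.
The external-loop class X is folded into E by default, reflecting the
biophysical similarity of the two contexts.

The one-hot parametrization carries exact linear dependencies (for each
offset the four sequence indicators and the six structure indicators both sum
to the same in-bounds mask, and the intercept equals the offset-0 sequence
block sum), so coefficients are identified only up to that null space; the
unpenalized fit returns the minimum-norm representative and
:meth:`WindowFeaturizer.null_space` exposes the basis.

A :class:`DegradationWindowModel` is built from a collection of records and a
channel, and ``fit`` / ``fit_boosted`` return results objects carrying the
estimates, diagnostics, prediction methods and serialization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import structure as st
from .records import PredictionSet, RnaRecord

logger = logging.getLogger(__name__)

SEQUENCE_ALPHABET = "ACGU"
STRUCTURE_ALPHABET = "HEIMBS"


def count_parameters(w: int) -> int:
    """Number of free parameters of the windowed linear model: (2w+1)*10 + 1."""
    if w < 0 or int(w) != w:
        raise ValueError(f"window half-width must be a non-negative integer, got {w!r}")
    return (2 * int(w) + 1) * (len(SEQUENCE_ALPHABET) + len(STRUCTURE_ALPHABET)) + 1


@dataclass(frozen=True)
class WindowFeaturizer:
    """One-hot (offset x indicator) featurization of sequence and loop type."""

    w: int = 12
    sequence_alphabet: str = SEQUENCE_ALPHABET
    structure_alphabet: str = STRUCTURE_ALPHABET
    merge_X_into_E: bool = True

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("window half-width must be non-negative")
        if self.merge_X_into_E and "E" not in self.structure_alphabet:
            raise ValueError("merge_X_into_E requires 'E' in the structure alphabet")

    @property
    def n_indicators(self) -> int:
        return len(self.sequence_alphabet) + len(self.structure_alphabet)

    @property
    def n_offsets(self) -> int:
        return 2 * self.w + 1

    @property
    def n_features(self) -> int:
        return self.n_offsets * self.n_indicators

    @property
    def n_parameters(self) -> int:
        """Features plus intercept."""
        return self.n_features + 1

    def feature_names(self) -> list[str]:
        """Flattened column labels, "<offset>:<indicator>"."""
        names = []
        for k in range(-self.w, self.w + 1):
            for ch in self.sequence_alphabet + self.structure_alphabet:
                names.append(f"{k:+d}:{ch}")
        return names

    def _encode_loops(self, loops: str) -> str:
        if self.merge_X_into_E:
            loops = loops.replace("X", "E")
        return loops

    def transform(self, sequence: str, loops: str) -> np.ndarray:
        """Feature matrix of shape (len(sequence), n_features); entries 0/1."""
        if len(sequence) != len(loops):
            raise ValueError(
                f"sequence length {len(sequence)} != loop annotation length {len(loops)}"
            )
        loops = self._encode_loops(loops)
        n = len(sequence)
        nseq = len(self.sequence_alphabet)
        nind = self.n_indicators
        seq_idx = np.empty(n, dtype=int)
        for i, ch in enumerate(sequence):
            j = self.sequence_alphabet.find(ch)
            if j < 0:
                raise ValueError(f"illegal sequence character {ch!r} at position {i}")
            seq_idx[i] = j
        loop_idx = np.empty(n, dtype=int)
        for i, ch in enumerate(loops):
            j = self.structure_alphabet.find(ch)
            if j < 0:
                raise ValueError(f"illegal loop class {ch!r} at position {i}")
            loop_idx[i] = j
        fm = np.zeros((n, self.n_features), dtype=float)
        rows = np.arange(n)
        for o, k in enumerate(range(-self.w, self.w + 1)):
            src = rows + k
            ok = (src >= 0) & (src < n)
            base = o * nind
            fm[rows[ok], base + seq_idx[src[ok]]] = 1.0
            fm[rows[ok], base + nseq + loop_idx[src[ok]]] = 1.0
        return fm

    def null_space(self) -> np.ndarray:
        """Orthonormal basis (columns) of the exact null space of the
        intercept-augmented design, in parameter order (features then
        intercept).

        For every offset the sequence-block sum equals the structure-block sum
        row-wise, and the intercept column equals the offset-0 sequence-block
        sum; coefficients are identified only modulo this span.
        """
        nseq = len(self.sequence_alphabet)
        nstr = len(self.structure_alphabet)
        nind = self.n_indicators
        p = self.n_parameters
        vecs = []
        for o in range(self.n_offsets):
            v = np.zeros(p)
            v[o * nind: o * nind + nseq] = 1.0
            v[o * nind + nseq: (o + 1) * nind] = -1.0
            vecs.append(v)
        v = np.zeros(p)
        v[-1] = 1.0
        center = self.w * nind
        v[center: center + nseq] = -1.0
        vecs.append(v)
        q, _ = np.linalg.qr(np.column_stack(vecs))
        return q

    def identifiable_projection(self, params: np.ndarray) -> np.ndarray:
        """Project a (features + intercept) parameter vector onto the
        orthogonal complement of the structural null space."""
        q = self.null_space()
        params = np.asarray(params, dtype=float)
        return params - q @ (q.T @ params)


def featurize(sequence: str, loops: str, featurizer: WindowFeaturizer | None = None) -> np.ndarray:
    """Functional wrapper around :meth:`WindowFeaturizer.transform`."""
    return (featurizer or WindowFeaturizer()).transform(sequence, loops)


def predict_linear(beta: np.ndarray, beta0: float, fm: np.ndarray) -> np.ndarray:
    """Per-position scores Y = F beta + beta0."""
    fm = np.asarray(fm, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if fm.ndim != 2 or fm.shape[1] != beta.shape[0]:
        raise ValueError(
            f"feature matrix has {fm.shape[1] if fm.ndim == 2 else '?'} columns, "
            f"coefficients have {beta.shape[0]}"
        )
    return fm @ beta + beta0


def _record_loops(record: RnaRecord) -> str:
    return record.loop_annotation()


class DegradationWindowModel:
    """Windowed degradation model for one measurement channel.

    Parameters
    ----------
    records : iterable of RnaRecord
        Training constructs; each must carry measurements for ``channel`` on
        its scored prefix.
    channel : str
        Measurement channel to model (e.g. ``"deg_Mg_pH10"``).
    featurizer : WindowFeaturizer, optional
        Defaults to the historical w = 12 configuration.
    """

    def __init__(self, records: Iterable[RnaRecord], channel: str,
                 featurizer: WindowFeaturizer | None = None):
        self.records = list(records)
        self.channel = channel
        self.featurizer = featurizer or WindowFeaturizer()
        blocks, targets = [], []
        for rec in self.records:
            if channel not in rec.values:
                raise KeyError(f"record {rec.id} lacks channel {channel!r}")
            if rec.seq_scored == 0:
                continue
            fm = self.featurizer.transform(rec.sequence, _record_loops(rec))
            blocks.append(fm[: rec.seq_scored])
            targets.append(rec.values[channel])
        if not blocks:
            raise ValueError("no scored positions in the training records")
        self.exog = np.vstack(blocks)
        self.endog = np.concatenate(targets)

    @classmethod
    def from_records(cls, records, channel, **kw) -> "DegradationWindowModel":
        return cls(records, channel, **kw)

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, ridge_lambda: float = 0.1) -> "LinearDegradationResults":
        """Least squares with an L2 penalty on the slopes (intercept free).

        ``ridge_lambda = 0`` solves ordinary least squares; because the
        one-hot design is exactly collinear the minimum-norm solution is
        returned and a condition warning is emitted.
        """
        if ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        x = np.hstack([self.exog, np.ones((self.nobs, 1))])
        p = x.shape[1]
        if ridge_lambda == 0:
            params, _, rank, sv = np.linalg.lstsq(x, self.endog, rcond=None)
            cond = sv[0] / sv[min(rank, len(sv)) - 1] if len(sv) else np.inf
            if rank < p:
                warnings.warn(
                    f"design is rank deficient (rank {rank} < {p}); "
                    "returning the minimum-norm solution",
                    RuntimeWarning,
                    stacklevel=2,
                )
        else:
            penalty = np.full(p, float(ridge_lambda))
            penalty[-1] = 0.0  # intercept unpenalized
            a = x.T @ x + np.diag(penalty)
            params = np.linalg.solve(a, x.T @ self.endog)
            sv = np.linalg.svd(x, compute_uv=False)
            rank = int(np.sum(sv > sv[0] * max(x.shape) * np.finfo(float).eps))
            cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        resid = self.endog - x @ params
        rmse = float(np.sqrt(np.mean(resid**2)))
        return LinearDegradationResults(
            featurizer=self.featurizer,
            channel=self.channel,
            beta=params[:-1],
            beta0=float(params[-1]),
            ridge_lambda=float(ridge_lambda),
            training_rmse=rmse,
            nobs=self.nobs,
            rank=int(rank),
            cond=float(cond),
        )

    def fit_boosted(self, n_estimators: int = 200, max_depth: int = 5,
                    learning_rate: float = 0.1, seed: int = 0,
                    **xgb_params) -> "BoostedDegradationResults":
        """Gradient-boosted trees over the same indicator columns
        (the DegScore-XGB variant); deterministic given ``seed``."""
        from xgboost import XGBRegressor

        booster = XGBRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            **xgb_params,
        )
        booster.fit(self.exog, self.endog)
        pred = booster.predict(self.exog)
        rmse = float(np.sqrt(np.mean((self.endog - pred) ** 2)))
        return BoostedDegradationResults(
            featurizer=self.featurizer,
            channel=self.channel,
            booster=booster,
            training_rmse=rmse,
            nobs=self.nobs,
        )


class _ResultsBase:
    """Prediction plumbing shared by the linear and boosted results."""

    featurizer: WindowFeaturizer
    channel: str

    def _predict_fm(self, fm: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, sequence: str, loops: str | None = None,
                structure: str | None = None) -> np.ndarray:
        """Per-position scores for one construct (full length).

        Provide either a loop-type annotation or a dot-bracket structure from
        which it is derived.
        """
        if loops is None:
            if structure is None:
                raise ValueError("provide loops or structure")
            loops = st.annotate_loop_types(st.parse_dotbracket(structure))
        fm = self.featurizer.transform(sequence, loops)
        return self._predict_fm(fm)

    def predict_records(self, records: Sequence[RnaRecord],
                        scored_only: bool = True) -> PredictionSet:
        out: dict[str, dict[str, np.ndarray]] = {}
        for rec in records:
            y = self.predict(rec.sequence, loops=_record_loops(rec))
            if scored_only:
                y = y[: rec.seq_scored]
            out[rec.id] = {self.channel: y}
        return PredictionSet(out)

    def plot_profile(self, record: RnaRecord, ax=None):
        """Plot measured vs predicted profile over the scored region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        y = self.predict(record.sequence, loops=_record_loops(record))
        ax.plot(y[: record.seq_scored], label="predicted")
        if self.channel in record.values:
            meas = record.values[self.channel]
            ax.plot(meas, label="measured", alpha=0.7)
            if self.channel in record.errors:
                err = record.errors[self.channel]
                x = np.arange(len(meas))
                ax.fill_between(x, meas - err, meas + err, alpha=0.2)
        ax.set_xlabel("position (nt)")
        ax.set_ylabel(self.channel)
        ax.legend(loc="upper right", fontsize="small")
        ax.set_title(record.id)
        return ax


@dataclass
class LinearDegradationResults(_ResultsBase):
    """Fitted windowed linear model: coefficients, diagnostics, prediction."""

    featurizer: WindowFeaturizer
    channel: str
    beta: np.ndarray
    beta0: float
    ridge_lambda: float
    training_rmse: float
    nobs: int
    rank: int
    cond: float
    metadata: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        """Full parameter vector, features then intercept."""
        return np.concatenate([self.beta, [self.beta0]])

    def _predict_fm(self, fm: np.ndarray) -> np.ndarray:
        return predict_linear(self.beta, self.beta0, fm)

    def coef_table(self) -> pd.DataFrame:
        """Coefficients as a tidy table (offset, indicator, kind, beta)."""
        fz = self.featurizer
        rows = []
        for name, b in zip(fz.feature_names(), self.beta):
            k, ind = name.split(":")
            kind = "sequence" if ind in fz.sequence_alphabet else "structure"
            rows.append((int(k), ind, kind, float(b)))
        return pd.DataFrame(rows, columns=["offset", "indicator", "kind", "beta"])

    def summary(self) -> str:
        fz = self.featurizer
        lines = [
            "Windowed linear degradation model",
            "=" * 44,
            f"channel:            {self.channel}",
            f"window half-width:  {fz.w}  ({fz.n_parameters} parameters)",
            f"ridge lambda:       {self.ridge_lambda:g}",
            f"n scored positions: {self.nobs}",
            f"design rank:        {self.rank} / {fz.n_parameters}",
            f"training RMSE:      {self.training_rmse:.5f}",
            f"intercept:          {self.beta0:.5f}",
            "",
            "largest-magnitude coefficients:",
        ]
        tab = self.coef_table()
        top = tab.reindex(tab.beta.abs().sort_values(ascending=False).index).head(10)
        for _, r in top.iterrows():
            lines.append(f"  {r.offset:+3d}:{r.indicator}  {r.beta:+.5f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        fz = self.featurizer
        doc = {
            "model": "windowed_linear",
            "window": fz.w,
            "sequence_alphabet": fz.sequence_alphabet,
            "structure_alphabet": fz.structure_alphabet,
            "merge_X_into_E": fz.merge_X_into_E,
            "channel": self.channel,
            "beta": {name: float(b) for name, b in zip(fz.feature_names(), self.beta)},
            "beta0": self.beta0,
            "metadata": {
                "ridge_lambda": self.ridge_lambda,
                "training_rmse": self.training_rmse,
                "nobs": self.nobs,
                "rank": self.rank,
                **self.metadata,
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearDegradationResults":
        """Load a serialized model; also accepts externally produced
        coefficient tables in the same keyed layout."""
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        fz = WindowFeaturizer(
            w=int(doc["window"]),
            sequence_alphabet=doc.get("sequence_alphabet", SEQUENCE_ALPHABET),
            structure_alphabet=doc.get("structure_alphabet", STRUCTURE_ALPHABET),
            merge_X_into_E=bool(doc.get("merge_X_into_E", True)),
        )
        names = fz.feature_names()
        table = doc["beta"]
        missing = [n for n in names if n not in table]
        if missing:
            raise ValueError(f"coefficient table missing entries, e.g. {missing[:3]}")
        beta = np.array([float(table[n]) for n in names])
        meta = dict(doc.get("metadata", {}))
        return cls(
            featurizer=fz,
            channel=doc["channel"],
            beta=beta,
            beta0=float(doc["beta0"]),
            ridge_lambda=float(meta.pop("ridge_lambda", np.nan)),
            training_rmse=float(meta.pop("training_rmse", np.nan)),
            nobs=int(meta.pop("nobs", 0)),
            rank=int(meta.pop("rank", 0)),
            cond=float("nan"),
            metadata=meta,
        )


@dataclass
class BoostedDegradationResults(_ResultsBase):
    """Fitted gradient-boosted variant over the same feature columns."""

    featurizer: WindowFeaturizer
    channel: str
    booster: object
    training_rmse: float
    nobs: int

    def _predict_fm(self, fm: np.ndarray) -> np.ndarray:
        return np.asarray(self.booster.predict(fm), dtype=float)

    def summary(self) -> str:
        b = self.booster
        return "\n".join([
            "Boosted windowed degradation model",
            "=" * 44,
            f"channel:            {self.channel}",
            f"window half-width:  {self.featurizer.w}",
            f"trees / depth / lr: {b.n_estimators} / {b.max_depth} / {b.learning_rate}",
            f"n scored positions: {self.nobs}",
            f"training RMSE:      {self.training_rmse:.5f}",
        ])


def fit_linear(records: Iterable[RnaRecord], channel: str,
               featurizer: WindowFeaturizer | None = None,
               ridge_lambda: float = 0.1) -> LinearDegradationResults:
    """Convenience wrapper: build the model and fit in one call."""
    return DegradationWindowModel(records, channel, featurizer).fit(ridge_lambda)


def fit_boosted(records: Iterable[RnaRecord], channel: str,
                featurizer: WindowFeaturizer | None = None,
                **hyperparams) -> BoostedDegradationResults:
    return DegradationWindowModel(records, channel, featurizer).fit_boosted(**hyperparams)
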