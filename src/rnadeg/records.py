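"""Data containers and file I/O.

The canonical dataset format is JSON lines, one record per line, using the
historical Kaggle column names (``sequence``, ``structure``,
``predicted_loop_type``, ``seq_length``, ``seq_scored``, the channel arrays
``reactivity``/``deg_Mg_pH10``/``deg_Mg_50C``/``deg_pH10``/``deg_50C`` and
their ``*_error_*`` counterparts, ``signal_to_noise`` and ``SN_filter``).
A JSON-array dialect is accepted as well.  Prediction tables are CSV with
columns id, position, channel, value; positions are 0-based everywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Measurement channels in the Round-I layout: SHAPE reactivity plus four
#: accelerated-degradation conditions.
CHANNELS = ("reactivity", "deg_Mg_pH10", "deg_Mg_50C", "deg_pH10", "deg_50C")

#: Degradation channels (everything except SHAPE reactivity).
DEG_CHANNELS = ("deg_Mg_pH10", "deg_Mg_50C", "deg_pH10", "deg_50C")

#: Channels scored in the blind evaluation (Round II collected only these).
SCORED_CHANNELS = ("reactivity", "deg_Mg_pH10", "deg_Mg_50C")


def error_field(channel: str) -> str:
    """Kaggle-dialect error-array column name for a channel."""
    if channel == "reactivity":
        return "reactivity_error"
    if channel.startswith("deg_"):
        return "deg_error_" + channel[len("deg_"):]
    return channel + "_error"


class RecordValidationError(ValueError):
    """A record violates the dataset invariants; names the record and field."""


@dataclass
class RnaRecord:
    """One RNA construct with per-nucleotide measurements.

    The scored region is the 5' prefix of length ``seq_scored``; the 3'
    remainder carries barcode/primer sequence and has no measurements.
    """

    id: str
    sequence: str
    structure: str
    predicted_loop_type: str = ""
    seq_scored: int | None = None
    values: dict[str, np.ndarray] = field(default_factory=dict)
    errors: dict[str, np.ndarray] = field(default_factory=dict)
    signal_to_noise: float | None = None
    SN_filter: int | None = None

    def __post_init__(self):
        if self.seq_scored is None:
            self.seq_scored = len(self.sequence)
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        self.errors = {c: np.asarray(v, dtype=float) for c, v in self.errors.items()}
        self.validate()

    @property
    def seq_length(self) -> int:
        return len(self.sequence)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.values)

    def validate(self) -> None:
        rid = self.id
        if len(self.structure) != len(self.sequence):
            raise RecordValidationError(
                f"record {rid}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.predicted_loop_type and len(self.predicted_loop_type) != len(self.sequence):
            raise RecordValidationError(
                f"record {rid}: loop annotation length mismatch"
            )
        if not 0 <= self.seq_scored <= len(self.sequence):
            raise RecordValidationError(
                f"record {rid}: seq_scored {self.seq_scored} outside [0, {len(self.sequence)}]"
            )
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise RecordValidationError(
                f"record {rid}: sequence contains non-ACGU characters {sorted(bad)}"
            )
        for channel, arr in self.values.items():
            if arr.shape != (self.seq_scored,):
                raise RecordValidationError(
                    f"record {rid}: channel {channel} has length {arr.shape} "
                    f"!= seq_scored {self.seq_scored}"
                )
        for channel, arr in self.errors.items():
            if arr.shape != (self.seq_scored,):
                raise RecordValidationError(
                    f"record {rid}: error array for {channel} has length "
                    f"{arr.shape} != seq_scored {self.seq_scored}"
                )
            if np.any(arr < 0):
                raise RecordValidationError(
                    f"record {rid}: negative error values in channel {channel}"
                )

    def loop_annotation(self) -> str:
        """Stored loop annotation, or one derived from the structure."""
        if self.predicted_loop_type:
            return self.predicted_loop_type
        from . import structure as st

        return st.annotate_loop_types(st.parse_dotbracket(self.structure))

    def to_dict(self) -> dict:
        d: dict = {
            "id": self.id,
            "sequence": self.sequence,
            "structure": self.structure,
            "predicted_loop_type": self.predicted_loop_type,
            "seq_length": self.seq_length,
            "seq_scored": self.seq_scored,
        }
        for channel, arr in self.values.items():
            d[channel] = arr.tolist()
        for channel, arr in self.errors.items():
            d[error_field(channel)] = arr.tolist()
        if self.signal_to_noise is not None:
            d["signal_to_noise"] = float(self.signal_to_noise)
        if self.SN_filter is not None:
            d["SN_filter"] = int(self.SN_filter)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RnaRecord":
        known = {"id", "sequence", "structure", "predicted_loop_type",
                 "seq_length", "seq_scored", "signal_to_noise", "SN_filter"}
        values, errors = {}, {}
        for channel in CHANNELS:
            if channel in d:
                values[channel] = d[channel]
            ef = error_field(channel)
            if ef in d:
                errors[channel] = d[ef]
            known |= {channel, ef}
        rec = cls(
            id=str(d["id"]),
            sequence=str(d["sequence"]),
            structure=str(d["structure"]),
            predicted_loop_type=str(d.get("predicted_loop_type", "")),
            seq_scored=int(d.get("seq_scored", len(d["sequence"]))),
            values=values,
            errors=errors,
            signal_to_noise=d.get("signal_to_noise"),
            SN_filter=d.get("SN_filter"),
        )
        declared = d.get("seq_length")
        if declared is not None and int(declared) != rec.seq_length:
            raise RecordValidationError(
                f"record {rec.id}: declared seq_length {declared} != {rec.seq_length}"
            )
        return rec


@dataclass
class PredictionSet:
    """Per-construct, per-channel predicted value arrays.

    ``values[id][channel]`` is a 1-D array aligned to positions 0..n-1 of the
    construct (typically the scored prefix).
    """

    values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.values = {
            rid: {c: np.asarray(v, dtype=float) for c, v in chans.items()}
            for rid, chans in self.values.items()
        }

    @property
    def ids(self) -> list[str]:
        return list(self.values)

    @property
    def channels(self) -> list[str]:
        chans: list[str] = []
        for per_id in self.values.values():
            for c in per_id:
                if c not in chans:
                    chans.append(c)
        return chans

    def __getitem__(self, rid: str) -> dict[str, np.ndarray]:
        return self.values[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.values

    def __len__(self) -> int:
        return len(self.values)

    def aligned_with(self, other: "PredictionSet") -> bool:
        if set(self.values) != set(other.values):
            return False
        for rid, chans in self.values.items():
            if set(chans) != set(other.values[rid]):
                return False
            for c, arr in chans.items():
                if arr.shape != other.values[rid][c].shape:
                    return False
        return True

    def allclose(self, other: "PredictionSet", **kw) -> bool:
        if not self.aligned_with(other):
            return False
        return all(
            np.allclose(arr, other.values[rid][c], **kw)
            for rid, chans in self.values.items()
            for c, arr in chans.items()
        )


# ---------------------------------------------------------------------------
# record files

def read_records(path, dialect: str = "json_lines") -> list[RnaRecord]:
    """Read a dataset of :class:`RnaRecord` from JSON lines or a JSON array."""
    path = Path(path)
    if dialect not in ("json_lines", "json_array"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    records: list[RnaRecord] = []
    if dialect == "json_array":
        try:
            payload = json.loads(text) if text.strip() else []
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: malformed JSON at line {e.lineno}") from e
        records = [RnaRecord.from_dict(d) for d in payload]
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}: malformed JSON at line {lineno}") from e
            records.append(RnaRecord.from_dict(d))
    if not records:
        logger.warning("%s: no records read", path)
    return records


def write_records(records: Iterable[RnaRecord], path, dialect: str = "json_lines") -> None:
    path = Path(path)
    dicts = [r.to_dict() for r in records]
    if dialect == "json_array":
        path.write_text(json.dumps(dicts, indent=1))
    elif dialect == "json_lines":
        path.write_text("".join(json.dumps(d) + "\n" for d in dicts))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by id; DNA-style T is normalized to U."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        s = str(rec.seq).upper()
        if "T" in s:
            logger.info("FASTA record %s: normalizing T to U", rec.id)
            s = s.replace("T", "U")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# prediction CSV

_PRED_HEADER = "# rnadeg predictions; positions are 0-based\n"


def write_predictions_csv(pred: PredictionSet, path) -> None:
    rows = [
        (rid, pos, channel, float(v))
        for rid, chans in pred.values.items()
        for channel, arr in chans.items()
        for pos, v in enumerate(arr)
    ]
    df = pd.DataFrame(rows, columns=["id", "position", "channel", "value"])
    with open(path, "w") as fh:
        fh.write(_PRED_HEADER)
        df.to_csv(fh, index=False)


def read_predictions_csv(path, expected_lengths: Mapping[str, int] | None = None) -> PredictionSet:
    """Read a prediction CSV.

    When ``expected_lengths`` (id -> number of positions) is given, every id
    must cover positions 0..n-1 contiguously in every channel it reports.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"id", "position", "channel", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"prediction CSV missing columns {sorted(missing)}")
    values: dict[str, dict[str, np.ndarray]] = {}
    for (rid, channel), grp in df.groupby(["id", "channel"], sort=False):
        rid = str(rid)
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        n = len(pos)
        if not np.array_equal(pos, np.arange(n)):
            raise ValueError(
                f"prediction CSV: id {rid} channel {channel} does not cover "
                f"positions 0..{n - 1} contiguously"
            )
        if expected_lengths is not None:
            want = expected_lengths.get(rid)
            if want is not None and n != want:
                raise ValueError(
                    f"prediction CSV: id {rid} channel {channel} has {n} "
                    f"positions, expected {want}"
                )
        values.setdefault(rid, {})[str(channel)] = grp["value"].to_numpy(dtype=float)
    return PredictionSet(values)


# ---------------------------------------------------------------------------
# base-pair probability matrices

def read_bpp(path) -> np.ndarray:
    """Whitespace-delimited square matrix with a one-line header giving N."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 1:
            raise ValueError("bpp file must start with a one-line header giving N")
        n = int(header[0])
        m = np.loadtxt(fh, dtype=float, ndmin=2)
    if m.shape != (n, n):
        raise ValueError(f"bpp matrix shape {m.shape} does not match header N={n}")
    return m


def write_bpp(m: np.ndarray, path) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("bpp matrix must be square")
    with open(path, "w") as fh:
        fh.write(f"{m.shape[0]}\n")
        np.savetxt(fh, m, fmt="%.8g")
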