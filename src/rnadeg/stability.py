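"""Whole-molecule stability: summed degradation rates and half-lives.

The overall degradation rate of an mRNA is the sum of the cleavage rates of
its dinucleotide linkages, k_total = sum_i k_i, and its hydrolysis half-life
is t_1/2 = ln 2 / k_total.  Per-nucleotide model outputs are used directly as
linkage-rate proxies.  Rates are unit-agnostic; the half-life comes out in
the reciprocal unit of the input rates.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .records import PredictionSet


def total_rate(rates, region: tuple[int, int] | None = None) -> float:
    """Sum per-linkage rates over a half-open region [start, end).

    The default region is the full vector.
    """
    rates = np.asarray(rates, dtype=float)
    if region is None:
        region = (0, len(rates))
    start, end = region
    if not 0 <= start <= end <= len(rates):
        raise ValueError(f"region {region} outside [0, {len(rates)})")
    if end == start:
        raise ValueError("empty region: total rate (and half-life) undefined")
    return float(rates[start:end].sum())


def half_life(k_total: float) -> float:
    """t_1/2 = ln 2 / k_total; requires a positive total rate."""
    if k_total <= 0:
        raise ValueError(f"half-life undefined for non-positive rate {k_total!r}")
    return math.log(2.0) / k_total


def sum_region_predictions(pred: PredictionSet,
                           regions: Mapping[str, tuple[int, int]],
                           channel: str | None = None,
                           length_normalize: bool = False) -> pd.DataFrame:
    """Per-construct summed (optionally length-normalized) predicted rates.

    Predictions must have been computed over the full sequence (so that
    interactions between untranslated and coding regions are reflected) and
    are then summed over each construct's probed window, e.g. its 5'UTR+CDS.

    Returns a table with columns id, region_start, region_end, k_total,
    half_life, length_normalized_rate.
    """
    missing = [rid for rid in pred.ids if rid not in regions]
    if missing:
        raise KeyError(f"no region given for ids: {missing}")
    rows = []
    for rid in pred.ids:
        chans = pred[rid]
        if channel is None:
            if len(chans) != 1:
                raise ValueError(
                    f"id {rid} has channels {sorted(chans)}; specify one"
                )
            arr = next(iter(chans.values()))
        else:
            arr = chans[channel]
        start, end = regions[rid]
        k = total_rate(arr, (start, end))
        rows.append({
            "id": rid,
            "region_start": start,
            "region_end": end,
            "k_total": k,
            "half_life": half_life(k) if k > 0 else np.nan,
            "length_normalized_rate": k / (end - start),
        })
    df = pd.DataFrame(rows)
    if length_normalize:
        df["value"] = df["length_normalized_rate"]
    else:
        df["value"] = df["k_total"]
    return df


def parse_region(spec: str, utr5: tuple[int, int] | None = None,
                 cds: tuple[int, int] | None = None) -> tuple[int, int]:
    """Resolve a region spec like "12:850" or "5'UTR+CDS" to a half-open
    interval, given annotated UTR/CDS boundaries where needed."""
    spec = spec.strip()
    if ":" in spec:
        a, b = spec.split(":")
        return int(a), int(b)
    if spec.upper() in ("5'UTR+CDS", "5UTR+CDS", "UTR5+CDS"):
        if utr5 is None or cds is None:
            raise ValueError("5'UTR+CDS region requires utr5 and cds boundaries")
        return utr5[0], cds[1]
    if spec.upper() == "CDS":
        if cds is None:
            raise ValueError("CDS region requires cds boundaries")
        return cds
    raise ValueError(f"unrecognized region spec {spec!r}")
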