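"""Synthetic dataset generation.

Emulates the statistical shape of the crowdsourced in-line hydrolysis data:
107-nt constructs scored over their first 68 nt (optionally mixed with
130/102-nt constructs), five measurement channels (SHAPE reactivity plus four
accelerated-degradation conditions), heteroscedastic counting-noise-like
per-position errors, sequence near-duplicates (design families), and a
planted linear dependence of the signal on windowed sequence and loop-type
context, plus additive motif effects (triloops most reactive; asymmetric
internal loops less stable than symmetric ones).

Structures come from a stochastic nested sampler constrained to
complementary pairs (AU, GC, GU) and hairpin loops of at least three
nucleotides; a hook accepts externally computed MFE structures for realism.
Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import structure as st
from .degmodel import LinearDegradationResults, WindowFeaturizer
from .evaluation import motif_positions
from .records import CHANNELS, PredictionSet, RnaRecord, write_records

_COMPLEMENT = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``noise_floor`` (a) and ``noise_slope`` (b) give the per-position
    measurement sd ``a + b * sqrt(max(true value, 0))``; ``latent_scale``
    adds a per-position latent shared across channels so that channels are
    correlated.  Reported error bars are the total sd of both components.
    ``fail_fraction`` of constructs are corrupted so that they fail the
    quality filter; ``duplicate_fraction`` are near-copies of earlier
    constructs (1-3 point mutations), mimicking the design families present
    in player-submitted data.
    """

    n_constructs: int = 200
    length: int = 107
    scored_length: int = 68
    long_fraction: float = 0.0       # fraction of 130/102-nt constructs
    long_length: int = 130
    long_scored_length: int = 102
    gc_content: float = 0.5
    prefix: str = ""                 # set to "GGAAA" to mimic the constant 5' start
    channels: tuple[str, ...] = CHANNELS
    window: int = 12
    beta_scale: float = 0.05
    beta0: float = 3.0
    motif_effects: dict = field(default_factory=lambda: {
        "triloop": 0.8,
        "asymmetric_internal": 0.3,
        "symmetric_internal": 0.1,
    })
    noise_floor: float = 0.05
    noise_slope: float = 0.15
    latent_scale: float = 0.1
    fail_fraction: float = 0.0
    duplicate_fraction: float = 0.1
    identifiable: bool = True        # plant coefficients in the identifiable subspace
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.gc_content <= 1:
            raise ValueError(f"gc_content must be in [0, 1], got {self.gc_content}")
        if self.scored_length > self.length or self.long_scored_length > self.long_length:
            raise ValueError("scored_length must not exceed length")
        for name in ("fail_fraction", "duplicate_fraction", "long_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def featurizer(self) -> WindowFeaturizer:
        return WindowFeaturizer(w=self.window)

    def noiseless(self) -> "SyntheticConfig":
        """Copy with every noise source switched off."""
        return replace(self, noise_floor=0.0, noise_slope=0.0, latent_scale=0.0,
                       fail_fraction=0.0)


def planted_models(cfg: SyntheticConfig) -> dict[str, LinearDegradationResults]:
    """The generating linear model per channel, drawn from cfg.seed.

    When ``cfg.identifiable`` the coefficients are projected onto the
    orthogonal complement of the featurization's structural null space, so
    that an unpenalized fit on noiseless data can recover them exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBE7A]))
    fz = cfg.featurizer()
    models = {}
    for channel in cfg.channels:
        params = np.concatenate([
            rng.normal(0.0, cfg.beta_scale, fz.n_features),
            [cfg.beta0],
        ])
        if cfg.identifiable:
            params = fz.identifiable_projection(params)
        models[channel] = LinearDegradationResults(
            featurizer=fz,
            channel=channel,
            beta=params[:-1],
            beta0=float(params[-1]),
            ridge_lambda=0.0,
            training_rmse=0.0,
            nobs=0,
            rank=fz.n_parameters,
            cond=np.nan,
            metadata={"planted": True, "seed": cfg.seed},
        )
    return models


def generate_sequences(cfg: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> list[str]:
    """Random ACGU sequences at the requested GC content (plus the optional
    constant 5' prefix); near-duplicates injected per ``duplicate_fraction``."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E95]))
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGU"))
    n_long = int(round(cfg.long_fraction * cfg.n_constructs))
    lengths = [cfg.long_length] * n_long + [cfg.length] * (cfg.n_constructs - n_long)
    seqs: list[str] = []
    for L in lengths:
        m = L - len(cfg.prefix)
        if m < 0:
            raise ValueError("prefix longer than construct length")
        body = "".join(rng.choice(alphabet, size=m, p=probs))
        seqs.append(cfg.prefix + body)
    n_dup = int(round(cfg.duplicate_fraction * len(seqs)))
    if n_dup and len(seqs) > 1:
        targets = rng.choice(np.arange(1, len(seqs)), size=n_dup, replace=False)
        for t in targets:
            src = int(rng.integers(0, t))
            if len(seqs[src]) != len(seqs[t]):
                continue  # only duplicate within a length class
            s = list(seqs[src])
            for _ in range(int(rng.integers(1, 4))):
                pos = int(rng.integers(len(cfg.prefix), len(s)))
                s[pos] = str(rng.choice(alphabet))
            seqs[t] = "".join(s)
    return seqs


def _complementary(a: str, b: str) -> bool:
    return (a, b) in _COMPLEMENT


def sample_structure(sequence: str, rng: np.random.Generator | int | None = None,
                     p_stop: float = 0.25, max_tries: int = 20) -> str:
    """Sample a valid nested structure for a sequence.

    Helices use complementary pairs only (AU, GC, GU wobble) and every
    hairpin loop keeps at least three unpaired nucleotides.  Purely a
    stochastic stand-in for a thermodynamic folder; an external folder hook
    can replace it (see :func:`make_dataset`).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n = len(sequence)
    partner = np.full(n, st.UNPAIRED, dtype=int)

    intervals = [(0, n - 1)]
    while intervals:
        lo, hi = intervals.pop()
        if hi - lo + 1 < 6 or rng.random() < p_stop:
            continue
        placed = False
        for _ in range(max_tries):
            i = int(rng.integers(lo, hi - 4))
            j = int(rng.integers(i + 5, hi + 1))
            if _complementary(sequence[i], sequence[j]):
                placed = True
                break
        if not placed:
            continue
        # extend the helix inward while complementary, keeping the loop >= 3
        stem = 0
        while (
            i + stem < j - stem
            and (j - stem) - (i + stem) - 1 >= 3
            and _complementary(sequence[i + stem], sequence[j - stem])
            and (stem == 0 or rng.random() < 0.85)
        ):
            partner[i + stem] = j - stem
            partner[j - stem] = i + stem
            stem += 1
        intervals.append((i + stem, j - stem))   # interior
        if i - lo >= 6:
            intervals.append((lo, i - 1))
        if hi - j >= 6:
            intervals.append((j + 1, hi))
    return st.PairTable(partner).to_dotbracket()


def plant_measurements(sequence: str, structure: str, cfg: SyntheticConfig,
                       rng: np.random.Generator | None = None,
                       models: dict[str, LinearDegradationResults] | None = None,
                       scored_length: int | None = None
                       ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-channel value and error arrays over the scored prefix.

    value = planted linear model + motif offsets + shared latent + noise;
    the reported error bar is the total sd of the latent and noise terms.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0B5]))
    models = models or planted_models(cfg)
    n_scored = scored_length if scored_length is not None else cfg.scored_length
    pt = st.parse_dotbracket(structure)
    offsets = np.zeros(len(sequence))
    bins = motif_positions(pt)
    for motif, eff in cfg.motif_effects.items():
        for pos in bins.get(motif, []):
            offsets[pos] += eff
    z = rng.standard_normal(len(sequence))  # latent shared across channels
    values, errors = {}, {}
    for channel in cfg.channels:
        base = models[channel].predict(sequence, structure=structure) + offsets
        sigma_noise = cfg.noise_floor + cfg.noise_slope * np.sqrt(np.clip(base, 0, None))
        total_sd = np.sqrt(cfg.latent_scale**2 + sigma_noise**2)
        noisy = base + cfg.latent_scale * z + sigma_noise * rng.standard_normal(len(sequence))
        values[channel] = noisy[:n_scored]
        errors[channel] = total_sd[:n_scored]
    return values, errors


def make_dataset(cfg: SyntheticConfig, path=None,
                 folder_hook: Callable[[str], str] | None = None) -> list[RnaRecord]:
    """Generate a full synthetic dataset (optionally serialized to JSONL).

    ``folder_hook`` maps sequence -> dot-bracket and substitutes the internal
    structure sampler (e.g. for externally computed MFE structures).
    A ``fail_fraction`` of constructs is corrupted to fail the quality filter
    (inflated SHAPE errors or an out-of-range degradation value); all records
    get their ``SN_filter`` flag set accordingly.
    """
    from .curation import FilterPolicy, apply_sn_filter

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDA7A]))
    models = planted_models(cfg)
    sequences = generate_sequences(cfg, np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x5E95])))
    n = len(sequences)
    n_fail = int(round(cfg.fail_fraction * n))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist()) if n_fail else set()
    policy = FilterPolicy()
    records: list[RnaRecord] = []
    for i, seq in enumerate(sequences):
        structure = folder_hook(seq) if folder_hook else sample_structure(seq, rng)
        n_scored = cfg.long_scored_length if len(seq) == cfg.long_length \
            and cfg.long_fraction > 0 else cfg.scored_length
        n_scored = min(n_scored, len(seq))
        values, errors = plant_measurements(
            seq, structure, cfg, rng, models=models, scored_length=n_scored
        )
        if i in fail_idx:
            if rng.random() < 0.5:
                # drown the SHAPE signal-to-noise
                sn_now = float(np.mean(values["reactivity"] / errors["reactivity"]))
                errors["reactivity"] = errors["reactivity"] * (2.0 * max(sn_now, 1.0))
            else:
                channel = str(rng.choice([c for c in cfg.channels if c != "reactivity"]))
                pos = int(rng.integers(n_scored))
                values[channel][pos] = policy.max_value_threshold + 5.0
        loops = st.annotate_loop_types(st.parse_dotbracket(structure))
        records.append(RnaRecord(
            id=f"synth_{cfg.seed:04d}_{i:05d}",
            sequence=seq,
            structure=structure,
            predicted_loop_type=loops,
            seq_scored=n_scored,
            values=values,
            errors=errors,
        ))
    try:
        apply_sn_filter(records, policy)
    except ValueError:
        # zero error bars (fully noiseless config): filter flags meaningless
        for rec in records:
            rec.SN_filter = None
    if path is not None:
        write_records(records, path)
    return records


def planted_prediction_set(records: Sequence[RnaRecord],
                           cfg: SyntheticConfig,
                           channels: Sequence[str] | None = None) -> PredictionSet:
    """Noise-free predictions of the generating model (including motif
    effects) on the scored prefix of each record — the ground truth that a
    perfect model would output."""
    models = planted_models(cfg)
    channels = list(channels or cfg.channels)
    out: dict[str, dict[str, np.ndarray]] = {}
    for rec in records:
        pt = st.parse_dotbracket(rec.structure)
        offsets = np.zeros(len(rec.sequence))
        for motif, eff in cfg.motif_effects.items():
            for pos in motif_positions(pt).get(motif, []):
                offsets[pos] += eff
        out[rec.id] = {}
        for channel in channels:
            y = models[channel].predict(rec.sequence, structure=rec.structure) + offsets
            out[rec.id][channel] = y[: rec.seq_scored]
    return PredictionSet(out)
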