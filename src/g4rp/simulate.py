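"""Synthetic G4RP-seq datasets with known ground truth.

The generator emulates the experimental design of a ligand-perturbed
G4-RNA precipitation study: a ribodepleted transcriptome of transcripts
with controlled length, G/C content and planted canonical pG4 motifs; a
latent per-transcript G4-folding propensity coupled to pG4 density through
a logistic link; and, per treatment condition (untreated plus two G4
ligands), one input library and replicate pulldown libraries with
negative-binomial read counts.

Sequence construction guarantees *exact* planted motif counts: loops and
background are built from a guanine-depleted alphabet in which no two
guanines are adjacent, so the only G-runs of length >= 3 are the planted
``GGG-loop-GGG-loop-GGG-loop-GGG`` cassettes, and cassettes are separated
by spacers longer than the maximal loop so they can neither merge nor
recombine. Every sequence is re-scanned after assembly and the run aborts
if the scanned count ever deviates from the target.

Count model: input counts are NB(mean = s_j * lambda_i, dispersion alpha)
with variance mu + alpha * mu^2; pulldown counts use mean
s_j * lambda_i * r_i where the capture rate is

    r_i = b + c * f_i,      f_i = expit(intercept + slope * density_i)

with ``density_i`` the planted-motif density in motifs/kb. Under a ligand,
responder transcripts have their folding propensity multiplied by
``responder_effect`` (capped at 1). Size factors ``s_j`` equalize expected
library totals, mimicking fixed sequencing depth per library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import INPUT_ASSAY, PULLDOWN_ASSAY, CountsMatrix
from .motifs import PRESETS, TranscriptRecord, count_pg4

#: Preset whose motif counts the generator controls exactly.
PLANT_PRESET = PRESETS["G3L1-7"]
#: Minimal gap between cassettes; one more than the longest loop, so tracts
#: of neighbouring cassettes can never be bridged by a legal loop.
CASSETTE_GAP = PLANT_PRESET.loop_max + 1

_LOOP_ALPHABET = "ACT"  # guanine-free loops keep planted counts exact


class SimulationError(ValueError):
    """Raised for invalid or infeasible generator requests."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic G4RP-seq study.

    Defaults describe the study conditions used throughout the test suite:
    2,000 transcripts of 500-3,000 nt, Poisson(3) planted G3L1-7 motifs,
    log-normal expression (median 300 expected input reads), NB dispersion
    0.05, background capture b = 0.002, capture gain c = 0.45, a logistic
    folding model over motifs/kb (intercept -3.0, slope 0.6, giving
    baseline folding propensities of roughly 0.05-0.7 across the density
    range), and 10% ligand responders with a 3-fold folding boost.
    ``gc_pg4_coupling`` raises the G/C target of pG4-dense transcripts,
    reproducing the real-transcriptome association between GC richness and
    pG4 density. These values were fixed by a one-time calibration of the
    generator (see the methods note) and are not tuned per analysis.
    """

    n_transcripts: int = 2000
    length_range: tuple[int, int] = (500, 3000)
    gc_target_range: tuple[float, float] = (0.35, 0.55)
    pg4_count_distribution: tuple = ("poisson", 3.0)
    pg4_count_max: int = 10
    gc_pg4_coupling: float = 0.03
    expression_log_mean: float = math.log(300.0)
    expression_log_sd: float = 1.0
    dispersion: float = 0.05
    background_capture: float = 0.002
    capture_gain: float = 0.45
    folding_model_slope: float = 0.6
    folding_model_intercept: float = -3.0
    responder_fraction: float = 0.1
    responder_effect: float = 3.0
    responder_selection: str = "uniform"  # or "low_pg4"
    conditions: tuple[str, ...] = ("untreated", "BRACO-19", "RHPS4")
    n_input_replicates: int = 1
    n_pulldown_replicates: int = 2
    library_sizes: float | dict[str, float] | None = None
    n_rrna: int = 0
    rrna_expression_multiplier: float = 50.0
    rrna_capture_multiplier: float = 0.3
    alphabet: str = "RNA"  # or "DNA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise SimulationError("n_transcripts must be positive")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise SimulationError(f"invalid length_range {self.length_range}")
        glo, ghi = self.gc_target_range
        if not (0.0 < glo <= ghi < 1.0):
            raise SimulationError(f"invalid gc_target_range {self.gc_target_range}")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if not (0.0 <= self.background_capture < 1.0):
            raise SimulationError("background_capture must be in [0, 1)")
        if self.capture_gain < 0:
            raise SimulationError("capture_gain must be >= 0")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise SimulationError("responder_fraction must be in [0, 1]")
        if self.responder_effect <= 0:
            raise SimulationError("responder_effect must be > 0")
        if self.responder_selection not in ("uniform", "low_pg4"):
            raise SimulationError(
                f"unknown responder_selection {self.responder_selection!r}"
            )
        if len(self.conditions) < 1:
            raise SimulationError("need at least one condition")
        if self.n_pulldown_replicates < 1 or self.n_input_replicates < 1:
            raise SimulationError("replicate counts must be >= 1")
        if self.alphabet not in ("RNA", "DNA"):
            raise SimulationError(f"alphabet must be 'RNA' or 'DNA', got {self.alphabet!r}")

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    @property
    def ligands(self) -> tuple[str, ...]:
        return tuple(self.conditions[1:])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        d["gc_target_range"] = list(self.gc_target_range)
        d["pg4_count_distribution"] = list(self.pg4_count_distribution)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("length_range", "gc_target_range", "pg4_count_distribution", "conditions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Latent per-transcript state realized by a simulation run.

    ``table`` is indexed by transcript id with columns ``expression``
    (expected input reads lambda_i), ``pg4_count``/``pg4_density_per_kb``
    (planted G3L1-7 motifs), ``folding_propensity`` (baseline f_i),
    ``responder_<ligand>``/``effect_<ligand>``, and the realized capture
    rate ``r_<condition>`` per condition. ``size_factors`` holds the
    per-sample scale s_j actually applied to the NB means.
    """

    table: pd.DataFrame
    size_factors: pd.Series
    config: SimulationConfig
    seed: int


def _draw_pg4_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    dist = cfg.pg4_count_distribution
    kind = dist[0]
    if kind == "poisson":
        k = int(rng.poisson(dist[1]))
    elif kind == "uniform":
        k = int(rng.integers(dist[1], dist[2] + 1))
    elif kind == "constant":
        k = int(dist[1])
    else:
        raise SimulationError(f"unknown pg4_count_distribution {dist!r}")
    if k < 0:
        raise SimulationError("pG4 target counts must be nonnegative")
    return min(k, cfg.pg4_count_max)


def _cassette(rng: np.random.Generator) -> str:
    """One exact G3L1-7 motif: four G3 tracts, G-free loops of 1-7 nt."""
    parts = ["GGG"]
    for _ in range(PLANT_PRESET.n_tracts - 1):
        loop_len = int(rng.integers(PLANT_PRESET.loop_min, PLANT_PRESET.loop_max + 1))
        loop = "".join(rng.choice(list(_LOOP_ALPHABET), size=loop_len))
        parts.append(loop)
        parts.append("GGG")
    return "".join(parts)


def _background(rng: np.random.Generator, length: int, n_g: int, n_c: int) -> str:
    """Random background of exact composition with no two adjacent guanines."""
    if length == 0:
        return ""
    arr = np.empty(length, dtype="<U1")
    arr[:] = ""
    if n_g > 0:
        # sample non-adjacent positions uniformly (stars-and-bars shift)
        base = rng.choice(length - (n_g - 1), size=n_g, replace=False)
        base.sort()
        gpos = base + np.arange(n_g)
        arr[gpos] = "G"
    n_rest = length - n_g
    n_t = (n_rest - n_c) // 2
    n_a = n_rest - n_c - n_t
    rest = np.array(list("C" * n_c + "A" * n_a + "T" * n_t), dtype="<U1")
    rng.shuffle(rest)
    arr[arr == ""] = rest
    return "".join(arr)


def _build_sequence(
    rng: np.random.Generator, index: int, length: int, gc_target: float, k: int
) -> str:
    """Assemble one transcript with exactly ``k`` planted motifs (DNA alphabet)."""
    cassettes = [_cassette(rng) for _ in range(k)]
    planted_len = sum(len(c) for c in cassettes)
    min_internal = CASSETTE_GAP * (k - 1) if k > 1 else 0
    bg_len = length - planted_len
    if bg_len < min_internal:
        raise SimulationError(
            f"transcript {index}: cannot fit {k} pG4 motifs "
            f"({planted_len} nt + {min_internal} nt spacers) in {length} nt"
        )
    planted_gc = sum(c.count("G") + c.count("C") for c in cassettes)
    total_gc = int(round(gc_target * length))
    bg_gc = min(max(total_gc - planted_gc, 0), bg_len)
    # keep background guanines sparse and non-adjacent
    n_g = min(bg_gc, int(0.04 * bg_len), (bg_len + 1) // 2)
    n_c = bg_gc - n_g
    bg = _background(rng, bg_len, n_g, n_c)
    # split the background into k+1 gaps; internal gaps >= CASSETTE_GAP
    extra = bg_len - min_internal
    gaps = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
    if k > 1:
        gaps[1:-1] += CASSETTE_GAP
    pieces = []
    cursor = 0
    for i, gap in enumerate(gaps):
        pieces.append(bg[cursor : cursor + gap])
        cursor += gap
        if i < k:
            pieces.append(cassettes[i])
    seq = "".join(pieces)
    assert len(seq) == length
    achieved = (seq.count("G") + seq.count("C")) / length
    if abs(achieved - gc_target) > 0.05:
        raise SimulationError(
            f"transcript {index}: G/C target {gc_target:.3f} infeasible with "
            f"{k} planted motifs in {length} nt (achieved {achieved:.3f})"
        )
    return seq


def simulate_transcriptome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_targets: bool = False,
):
    """Generate transcript sequences with exactly controlled pG4 content.

    Returns a list of :class:`~g4rp.motifs.TranscriptRecord` (and, with
    ``return_targets=True``, a DataFrame of the per-transcript targets:
    planted count, length, G/C target). Deterministic given
    ``config.seed``. Raises :class:`SimulationError` naming the transcript
    index if a request is infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    glo, ghi = config.gc_target_range
    records: list[TranscriptRecord] = []
    targets: list[dict] = []
    specs: list[tuple[str, str | None]] = [
        (f"tx{i + 1:05d}", None) for i in range(config.n_transcripts)
    ]
    specs += [(f"rrna{j + 1:03d}", "rRNA") for j in range(config.n_rrna)]
    for index, (tx_id, biotype) in enumerate(specs):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        k = 0 if biotype == "rRNA" else _draw_pg4_count(rng, config)
        density_kb = 1000.0 * k / length
        gc_target = float(
            np.clip(rng.uniform(glo, ghi) + config.gc_pg4_coupling * density_kb, 0.25, 0.80)
        )
        seq = None
        for _attempt in range(5):
            candidate = _build_sequence(rng, index, length, gc_target, k)
            if count_pg4(candidate, PLANT_PRESET) == k:
                seq = candidate
                break
        if seq is None:  # pragma: no cover - construction is exact by design
            raise SimulationError(
                f"transcript {index}: planted motif count not recovered after 5 attempts"
            )
        if config.alphabet == "RNA":
            seq = seq.replace("T", "U")
        records.append(TranscriptRecord.from_sequence(tx_id, seq, biotype=biotype))
        targets.append(
            {
                "transcript_id": tx_id,
                "length": length,
                "gc_target": gc_target,
                "pg4_target": k,
                "biotype": biotype or "mRNA",
            }
        )
    if return_targets:
        return records, pd.DataFrame(targets).set_index("transcript_id")
    return records


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts with variance mu + dispersion * mu^2 (zero mean -> zero)."""
    size = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    if positive.any():
        out[positive] = rng.negative_binomial(size, p[positive])
    return out


def simulate_g4rp_counts(
    transcripts: Sequence[TranscriptRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountsMatrix, SimulationTruth]:
    """Simulate the per-condition input + pulldown count design.

    Sample ids are ``{condition}_input_{r}`` and ``{condition}_G4RP_{r}``.
    Deterministic given ``config.seed`` (or the supplied generator).
    """
    if len(transcripts) == 0:
        raise SimulationError("transcripts must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(transcripts)
    ids = [t.id for t in transcripts]

    lam = rng.lognormal(config.expression_log_mean, config.expression_log_sd, size=n)
    is_rrna = np.array([t.biotype == "rRNA" for t in transcripts])
    lam = np.where(is_rrna, lam * config.rrna_expression_multiplier, lam)

    density_kb = np.array(
        [1000.0 * t.pg4_counts[PLANT_PRESET.name] / t.length for t in transcripts]
    )
    folding = expit(
        config.folding_model_intercept + config.folding_model_slope * density_kb
    )

    n_resp = int(round(config.responder_fraction * n))
    if config.responder_selection == "low_pg4":
        weights = np.exp(-density_kb)
        weights = weights / weights.sum()
    else:
        weights = None
    responder: dict[str, np.ndarray] = {}
    effect: dict[str, np.ndarray] = {}
    for lig in config.ligands:
        flags = np.zeros(n, dtype=bool)
        if n_resp > 0:
            chosen = rng.choice(n, size=n_resp, replace=False, p=weights)
            flags[chosen] = True
        responder[lig] = flags
        effect[lig] = np.where(flags, config.responder_effect, 1.0)

    b, c = config.background_capture, config.capture_gain
    rate: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        if cond == config.reference_condition:
            f_eff = folding
        else:
            f_eff = np.minimum(1.0, folding * effect[cond])
        r = b + c * f_eff
        # residual rRNA escapes capture: depleted below background
        r = np.where(is_rrna, b * config.rrna_capture_multiplier, r)
        rate[cond] = r

    sample_rows: list[dict] = []
    raw_means: list[np.ndarray] = []
    for cond in config.conditions:
        for rep in range(1, config.n_input_replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"{cond}_input_{rep}",
                    "condition": cond,
                    "assay": INPUT_ASSAY,
                    "replicate": rep,
                }
            )
            raw_means.append(lam)
        for rep in range(1, config.n_pulldown_replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"{cond}_G4RP_{rep}",
                    "condition": cond,
                    "assay": PULLDOWN_ASSAY,
                    "replicate": rep,
                }
            )
            raw_means.append(lam * rate[cond])

    base_depth = float(lam.sum())
    size_factors = {}
    counts = {}
    for row, raw in zip(sample_rows, raw_means):
        sid = row["sample_id"]
        if config.library_sizes is None:
            target = base_depth
        elif isinstance(config.library_sizes, dict):
            try:
                target = float(config.library_sizes[sid])
            except KeyError:
                raise SimulationError(f"library_sizes missing sample {sid!r}") from None
        else:
            target = float(config.library_sizes)
        if target <= 0:
            raise SimulationError(f"library size for {sid!r} must be positive")
        expected = float(raw.sum())
        s = target / expected if expected > 0 else 1.0
        size_factors[sid] = s
        counts[sid] = _nb_draw(rng, s * raw, config.dispersion)

    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"))
    cm = CountsMatrix(counts=counts_df, samples=samples)

    truth_table = pd.DataFrame(
        {
            "expression": lam,
            "pg4_count": [t.pg4_counts[PLANT_PRESET.name] for t in transcripts],
            "pg4_density_per_kb": density_kb,
            "folding_propensity": folding,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    for lig in config.ligands:
        truth_table[f"responder_{lig}"] = responder[lig]
        truth_table[f"effect_{lig}"] = effect[lig]
    for cond in config.conditions:
        truth_table[f"r_{cond}"] = rate[cond]
    truth = SimulationTruth(
        table=truth_table,
        size_factors=pd.Series(size_factors, name="size_factor"),
        config=config,
        seed=config.seed,
    )
    return cm, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], CountsMatrix, SimulationTruth]:
    """Sequences and counts from a single RNG stream seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = simulate_transcriptome(config, rng=rng)
    cm, truth = simulate_g4rp_counts(records, config, rng=rng)
    return records, cm, truth


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A no-enrichment variant (capture gain 0, so r_i = b for every transcript)."""
    cfg = config or SimulationConfig()
    return replace(cfg, capture_gain=0.0, **overrides)
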