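"""Count normalization and enrichment scoring for pulldown/input designs.

The G4RP-seq design sequences, for every treatment condition, one input
library (pre-capture lysate) and replicate pulldown (BioTASQ-captured)
libraries. After median-of-ratios normalization the per-gene Enrichment
Score is the ratio of mean pulldown signal to mean input signal,

    ES_i = (mean pulldown_i + eps) / (mean input_i + eps),

with a small pseudocount ``eps`` keeping the score finite, and the
Enrichment Score Change for a ligand treatment is the ratio of Enrichment
Scores,

    dES_i = ES_i(treated) / ES_i(untreated).

Genes are filtered by normalized mean read count (> 50 "expressed",
>= 500 "abundant") and dES > 1.75 flags ligand-induced targets; ranked
lists by ES (baseline landscape) and dES (ligand response) feed the
landscape statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INPUT_ASSAY = "input"
PULLDOWN_ASSAY = "G4RP"

#: Default thresholds: strict > 50 for "expressed", >= 500 for "abundant"
#: (the published methods state the expression filter strictly; the
#: abundance boundary is stated both ways, so strictness is a flag), and
#: fold change > 1.75 for ligand induction.
MIN_MEAN = 50.0
ABUNDANT_MEAN = 500.0
DES_THRESHOLD = 1.75
PSEUDOCOUNT = 0.5


@dataclass
class CountsMatrix:
    """Gene x sample integer counts plus a sample sheet.

    ``counts``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition``, ``assay`` (``input``/``G4RP``) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        missing = [c for c in counts.columns if c not in samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        extra = [s for s in samples.index if s not in counts.columns]
        if extra:
            raise ValueError(f"sample sheet rows without a counts column: {extra}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        bad_assay = set(samples["assay"]) - {INPUT_ASSAY, PULLDOWN_ASSAY}
        if bad_assay:
            raise ValueError(f"unknown assay labels: {sorted(bad_assay)}")
        for cond in samples.loc[samples["assay"] == PULLDOWN_ASSAY, "condition"].unique():
            if self.input_samples(cond).empty:
                raise ValueError(f"condition {cond!r} has pulldown samples but no input")
        # keep the sheet in counts-column order
        self.samples = samples.loc[counts.columns]
        self.samples.index.name = "sample_id"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def input_samples(self, condition: str) -> pd.Index:
        m = (self.samples["condition"] == condition) & (self.samples["assay"] == INPUT_ASSAY)
        return self.samples.index[m]

    def pulldown_samples(self, condition: str) -> pd.Index:
        m = (self.samples["condition"] == condition) & (self.samples["assay"] == PULLDOWN_ASSAY)
        return self.samples.index[m]


def compute_size_factors(
    counts: CountsMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, ``s_j`` is the median over reference genes of
    ``counts_ij / geomean_i`` where ``geomean_i`` is the per-gene geometric
    mean across samples. Genes with a zero in any sample are excluded from
    the reference set; if no gene is positive in every sample, pass
    ``pseudo_reference=True`` to compute the per-gene geometric mean over
    positive entries only (genes positive in at least two samples).
    """
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    mat = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.isfinite(logs).all(axis=1)
    if all_positive.any():
        log_geo = logs[all_positive].mean(axis=1)
        ratios = mat[all_positive] / np.exp(log_geo)[:, None]
    elif pseudo_reference:
        pos = mat > 0
        usable = pos.sum(axis=1) >= 2
        if not usable.any():
            raise ValueError("no gene is positive in at least two samples")
        with np.errstate(invalid="ignore"):
            log_geo = np.where(pos[usable], logs[usable], np.nan)
        log_geo = np.nanmean(log_geo, axis=1)
        ratios = np.where(pos[usable], mat[usable] / np.exp(log_geo)[:, None], np.nan)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; re-run with "
            "pseudo_reference=True to use a positive-entry pseudo-reference"
        )
    with np.errstate(invalid="ignore"):
        s = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("degenerate size factors (a sample has no usable ratios)")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=df.columns, name="size_factor")


def normalize_counts(
    counts: CountsMatrix | pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    return df.div(size_factors.loc[df.columns], axis=1)


def mean_read_count(normalized: pd.DataFrame) -> pd.Series:
    """Per-gene mean normalized read count across all samples."""
    return normalized.mean(axis=1).rename("mean_count")


def enrichment_score(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str,
    pseudocount: float = PSEUDOCOUNT,
    pooled_input: bool = False,
) -> pd.Series:
    """Per-gene ES for one condition: (pulldown mean + eps)/(input mean + eps).

    ``pooled_input=True`` uses the inputs of all conditions as the
    denominator instead of the condition-matched input.
    """
    pull = samples.index[
        (samples["condition"] == condition) & (samples["assay"] == PULLDOWN_ASSAY)
    ]
    if pooled_input:
        inp = samples.index[samples["assay"] == INPUT_ASSAY]
    else:
        inp = samples.index[
            (samples["condition"] == condition) & (samples["assay"] == INPUT_ASSAY)
        ]
    if len(pull) == 0:
        raise ValueError(f"condition {condition!r} has no pulldown samples")
    if len(inp) == 0:
        raise ValueError(f"condition {condition!r} has no input sample")
    es = (normalized[pull].mean(axis=1) + pseudocount) / (
        normalized[inp].mean(axis=1) + pseudocount
    )
    return es.rename(f"es_{condition}")


def enrichment_score_change(es_treated: pd.Series, es_untreated: pd.Series) -> pd.Series:
    """Per-gene dES = ES(treated)/ES(untreated); undefined entries become NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        des = es_treated / es_untreated
    return des.replace([np.inf, -np.inf], np.nan)


@dataclass
class EnrichmentTable:
    """Per-gene enrichment results with filter flags and ranks.

    ``frame`` columns: ``mean_count``; per condition ``input_mean_*``,
    ``pulldown_mean_*``, ``es_*`` and ``rank_es_*``; per ligand ``des_*``,
    ``induced_*`` (expressed and dES > threshold), ``top_*`` (induced and
    abundant — the high-confidence list) and ``rank_des_*``; plus the
    ``expressed``/``abundant`` flags.
    """

    frame: pd.DataFrame
    reference: str
    ligands: tuple[str, ...]
    params: dict = field(default_factory=dict)


def _ranks_desc(values: pd.Series, mask: pd.Series) -> pd.Series:
    """1-based descending ranks over ``mask``; ties broken by gene id."""
    sub = values[mask & values.notna()].sort_index()
    order = sub.sort_values(ascending=False, kind="mergesort")
    ranks = pd.Series(np.nan, index=values.index)
    ranks.loc[order.index] = np.arange(1, len(order) + 1, dtype=float)
    return ranks


def filter_and_rank(
    frame: pd.DataFrame,
    reference: str,
    ligands: Sequence[str],
    min_mean: float = MIN_MEAN,
    abundant_mean: float = ABUNDANT_MEAN,
    des_threshold: float = DES_THRESHOLD,
    strict_abundant: bool = False,
    conditions: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Apply the expression/abundance/induction filters and rank genes.

    Flags: ``expressed`` iff mean count strictly > ``min_mean``; ``abundant``
    iff mean count >= ``abundant_mean`` (strictly > with
    ``strict_abundant``); per ligand ``induced`` iff expressed and
    dES > ``des_threshold``. Genes failing the expression filter carry NaN
    ranks and never enter top/bottom lists.
    """
    out = frame.copy()
    mean = out["mean_count"]
    out["expressed"] = mean > min_mean
    out["abundant"] = (mean > abundant_mean) if strict_abundant else (mean >= abundant_mean)
    conditions = list(conditions) if conditions is not None else [reference, *ligands]
    for cond in conditions:
        out[f"rank_es_{cond}"] = _ranks_desc(out[f"es_{cond}"], out["expressed"])
    for lig in ligands:
        des = out[f"des_{lig}"]
        out[f"induced_{lig}"] = out["expressed"] & (des > des_threshold) & des.notna()
        out[f"top_{lig}"] = out[f"induced_{lig}"] & out["abundant"]
        out[f"rank_des_{lig}"] = _ranks_desc(des, out["expressed"])
    return out


def score_dataset(
    cm: CountsMatrix,
    reference: str = "untreated",
    pseudocount: float = PSEUDOCOUNT,
    min_mean: float = MIN_MEAN,
    abundant_mean: float = ABUNDANT_MEAN,
    des_threshold: float = DES_THRESHOLD,
    strict_abundant: bool = False,
    pooled_input: bool = False,
    des_mode: str = "es_ratio",
    pseudo_reference: bool = False,
) -> EnrichmentTable:
    """Full scoring pipeline: normalize, ES per condition, dES per ligand, filters, ranks.

    ``des_mode`` selects how dES is computed: ``"es_ratio"`` (default) is the
    ratio of input-adjusted Enrichment Scores; ``"pulldown_ratio"`` is the
    input-unadjusted treated/untreated pulldown fold change.
    """
    if reference not in cm.conditions:
        raise ValueError(f"reference condition {reference!r} not in sample sheet")
    if des_mode not in ("es_ratio", "pulldown_ratio"):
        raise ValueError(f"unknown des_mode {des_mode!r}")
    ligands = tuple(c for c in cm.conditions if c != reference)
    size = compute_size_factors(cm, pseudo_reference=pseudo_reference)
    norm = normalize_counts(cm, size)
    frame = pd.DataFrame({"mean_count": mean_read_count(norm)})
    es: dict[str, pd.Series] = {}
    for cond in cm.conditions:
        pull = cm.pulldown_samples(cond)
        inp = cm.input_samples(cond)
        frame[f"input_mean_{cond}"] = norm[inp].mean(axis=1)
        frame[f"pulldown_mean_{cond}"] = norm[pull].mean(axis=1)
        es[cond] = enrichment_score(
            norm, cm.samples, cond, pseudocount=pseudocount, pooled_input=pooled_input
        )
        frame[f"es_{cond}"] = es[cond]
    for lig in ligands:
        if des_mode == "es_ratio":
            des = enrichment_score_change(es[lig], es[reference])
        else:
            des = enrichment_score_change(
                frame[f"pulldown_mean_{lig}"] + pseudocount,
                frame[f"pulldown_mean_{reference}"] + pseudocount,
            )
        frame[f"des_{lig}"] = des
    frame = filter_and_rank(
        frame,
        reference,
        ligands,
        min_mean=min_mean,
        abundant_mean=abundant_mean,
        des_threshold=des_threshold,
        strict_abundant=strict_abundant,
        conditions=cm.conditions,
    )
    params = {
        "reference": reference,
        "pseudocount": pseudocount,
        "min_mean": min_mean,
        "abundant_mean": abundant_mean,
        "des_threshold": des_threshold,
        "strict_abundant": strict_abundant,
        "pooled_input": pooled_input,
        "des_mode": des_mode,
    }
    return EnrichmentTable(frame=frame, reference=reference, ligands=ligands, params=params)
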