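"""Quantitative readouts for the supporting in vitro assays.

Covers four plate-style computations: FRET-melting half-transition
temperatures (T1/2 and ligand-induced dT1/2), bead capture efficiency of a
biotinylated probe relative to no-probe controls, pulldown qPCR fold
changes by the delta-delta-Ct method with the pulldown Ct referenced to
the matched input, and LDx dose interpolation from normalized growth
dose-response curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class MeltCurve:
    """A temperature/emission series from a melt experiment.

    Temperatures are degrees Celsius, strictly increasing; emission is in
    arbitrary fluorescence units and rises as the labeled duplex/quadruplex
    melts.
    """

    temperatures: np.ndarray
    emission: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.shape != self.emission.shape:
            raise ValueError("temperatures and emission must be 1-D and equal length")
        if len(self.temperatures) < 2:
            raise ValueError("a melt curve needs at least two points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")

    def normalized_emission(self) -> np.ndarray:
        lo, hi = self.emission.min(), self.emission.max()
        if hi == lo:
            raise ValueError(f"melt curve {self.label!r} is flat; cannot normalize")
        return (self.emission - lo) / (hi - lo)


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Min-max normalize emission to [0, 1] using the curve's own extrema."""
    return MeltCurve(curve.temperatures, curve.normalized_emission(), curve.label)


def t_half(curve: MeltCurve) -> float:
    """Temperature of the first upward crossing of normalized emission 0.5.

    Linearly interpolated between the bracketing samples; a point sitting
    exactly at 0.5 is its own crossing. Multiple upward crossings trigger a
    warning and the first is returned; no crossing raises ``ValueError``.
    """
    y = curve.normalized_emission()
    t = curve.temperatures
    crossings = [
        i for i in range(1, len(y)) if y[i - 1] < 0.5 <= y[i]
    ]
    if not crossings:
        raise ValueError(f"melt curve {curve.label!r} never crosses 0.5 upward")
    if len(crossings) > 1:
        warnings.warn(
            f"melt curve {curve.label!r} crosses 0.5 upward {len(crossings)} times; "
            "using the first crossing",
            stacklevel=2,
        )
    i = crossings[0]
    frac = (0.5 - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def delta_t_half(with_ligand: MeltCurve, without_ligand: MeltCurve) -> float:
    """Stabilization dT1/2 = T1/2(ligand) - T1/2(no ligand) for one curve pair."""
    return t_half(with_ligand) - t_half(without_ligand)


def mean_delta_t_half(pairs: Iterable[tuple[MeltCurve, MeltCurve]]) -> float:
    """Mean dT1/2 over replicate (with, without) curve pairs.

    Replicates are paired before averaging: each pair is subtracted first
    and the differences are averaged.
    """
    deltas = [delta_t_half(w, wo) for w, wo in pairs]
    if not deltas:
        raise ValueError("no replicate pairs supplied")
    return float(np.mean(deltas))


def capture_efficiency(
    sample_signals: Sequence[float], control_signals: Sequence[float]
) -> float:
    """Fold enrichment of probe wells over no-probe control wells.

    The control wells define 1.0; the result is mean(sample)/mean(control).
    Degree-0 homogeneous: common scaling of all wells cancels.
    """
    sample = np.asarray(sample_signals, dtype=float)
    control = np.asarray(control_signals, dtype=float)
    if sample.size == 0 or control.size == 0:
        raise ValueError("need at least one sample and one control well")
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    return float(sample.mean() / cmean)


@dataclass
class QPCRMeasurement:
    """Pulldown/input Ct values (technical triplicates) for one target.

    ``delta_ct`` is mean Ct(pulldown) - mean Ct(input): the pulldown signal
    normalized to the matched input control, on the Ct scale.
    """

    target: str
    condition: str
    ct_pulldown: Sequence[float]
    ct_input: Sequence[float]

    def __post_init__(self) -> None:
        for name, vals in (("ct_pulldown", self.ct_pulldown), ("ct_input", self.ct_input)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} is empty for target {self.target!r}")
            if (arr <= 0).any():
                raise ValueError(f"{name} must be positive for target {self.target!r}")

    @property
    def n_replicates(self) -> tuple[int, int]:
        return (len(self.ct_pulldown), len(self.ct_input))

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_pulldown) - np.mean(self.ct_input))


def qpcr_fold_change(
    treated: QPCRMeasurement, untreated: QPCRMeasurement, efficiency: float = 2.0
) -> float:
    """Delta-delta-Ct fold change of pulldown signal, treated vs untreated.

    Technical replicates are averaged on the Ct scale before differencing;
    fold = efficiency ** (dCt_untreated - dCt_treated). A perfect doubling
    per cycle (efficiency 2) is assumed by default.
    """
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    return float(efficiency ** (untreated.delta_ct - treated.delta_ct))


@dataclass
class DoseResponseCurve:
    """Growth (confluency) versus ligand dose.

    ``normalization_max``/``normalization_min`` default to the curve's own
    extrema — the maximum and minimum achievable confluency under the assay
    conditions; override them for plate-wide normalization.
    """

    doses: np.ndarray
    confluency: np.ndarray
    label: str = ""
    normalization_max: float | None = None
    normalization_min: float | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.confluency = np.asarray(self.confluency, dtype=float)
        if self.doses.shape != self.confluency.shape or self.doses.ndim != 1:
            raise ValueError("doses and confluency must be 1-D and equal length")
        if len(self.doses) < 2:
            raise ValueError("a dose-response curve needs at least two doses")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if (self.doses < 0).any():
            raise ValueError("doses must be nonnegative")

    def normalized_response(self) -> np.ndarray:
        hi = self.normalization_max if self.normalization_max is not None else self.confluency.max()
        lo = self.normalization_min if self.normalization_min is not None else self.confluency.min()
        if hi <= lo:
            raise ValueError("normalization max must exceed min")
        return (self.confluency - lo) / (hi - lo)


def ld_dose(curve: DoseResponseCurve, x: float) -> float:
    """Dose producing x% growth inhibition (normalized response = 1 - x/100).

    Interpolates linearly in log10(dose) between the bracketing observed
    doses (serial-dilution spacing); refuses to extrapolate outside the
    observed response range.
    """
    if not (0 < x < 100):
        raise ValueError(f"x must be in (0, 100), got {x}")
    y = curve.normalized_response()
    target = 1.0 - x / 100.0
    for i, yi in enumerate(y):
        if yi == target:
            return float(curve.doses[i])
    for i in range(len(y) - 1):
        if y[i] > target > y[i + 1]:
            d1, d2 = curve.doses[i], curve.doses[i + 1]
            if d1 <= 0 or d2 <= 0:
                raise ValueError("log-dose interpolation requires positive doses")
            frac = (y[i] - target) / (y[i] - y[i + 1])
            return float(10 ** (np.log10(d1) + frac * (np.log10(d2) - np.log10(d1))))
    raise ValueError(
        f"LD{x:g} target response {target:.3f} outside the observed range "
        f"[{y.min():.3f}, {y.max():.3f}] of curve {curve.label!r}"
    )


# ---------------------------------------------------------------------------
# long-format CSV readers

def read_melt_curves(path) -> dict[str, MeltCurve]:
    """Read melt curves from CSV columns ``temperature,emission,label``."""
    df = pd.read_csv(path)
    required = {"temperature", "emission"}
    if not required <= set(df.columns):
        raise ValueError(f"melt table must have columns {sorted(required)}")
    if "label" not in df.columns:
        df["label"] = "curve"
    out = {}
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("temperature")
        out[str(label)] = MeltCurve(
            grp["temperature"].to_numpy(), grp["emission"].to_numpy(), str(label)
        )
    return out


def read_qpcr_table(path) -> list[QPCRMeasurement]:
    """Read qPCR Cts from CSV columns ``target,condition,assay,ct``.

    ``assay`` must be ``pulldown`` or ``input``; replicate rows share the
    same (target, condition, assay).
    """
    df = pd.read_csv(path)
    required = {"target", "condition", "assay", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    out = []
    for (target, condition), grp in df.groupby(["target", "condition"], sort=False):
        pull = grp.loc[grp["assay"] == "pulldown", "ct"].tolist()
        inp = grp.loc[grp["assay"] == "input", "ct"].tolist()
        if not inp:
            raise ValueError(f"missing input Ct for {target!r}/{condition!r}")
        if not pull:
            raise ValueError(f"missing pulldown Ct for {target!r}/{condition!r}")
        out.append(QPCRMeasurement(str(target), str(condition), pull, inp))
    return out


def read_dose_response(path) -> dict[str, DoseResponseCurve]:
    """Read dose-response curves from CSV columns ``dose,confluency[,label]``.

    Replicate rows at the same dose are averaged.
    """
    df = pd.read_csv(path)
    required = {"dose", "confluency"}
    if not required <= set(df.columns):
        raise ValueError(f"dose-response table must have columns {sorted(required)}")
    if "label" not in df.columns:
        df["label"] = "curve"
    out = {}
    for label, grp in df.groupby("label", sort=False):
        avg = grp.groupby("dose", sort=True)["confluency"].mean()
        out[str(label)] = DoseResponseCurve(
            avg.index.to_numpy(), avg.to_numpy(), str(label)
        )
    return out
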