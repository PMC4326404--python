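"""Spike-in based single-channel normalization.

Three stages, applied on the log10 scale and returned on the linear scale:

1. **Anchoring** — each sample's log10 signals are shifted additively so
   that the designated anchor spike-in (default ``E1A_r60_a20``, log10
   relative concentration 3.83) reads exactly its own concentration in
   every sample.  The anchor is thereby a fixed point of the subsequent
   concentration mapping.
2. **Concentration interpolation** — for each sample, the log10 signals of
   the spike-in panel define a monotone piecewise-linear calibration from
   log10 signal to log10 relative concentration; every probe's signal is
   mapped through it.  Non-monotone spike responses are repaired by
   pool-adjacent-violators on the signal coordinate; values outside the
   spike range are mapped by linear extension of the terminal segments.
3. **Percentile scaling** — each sample is divided by the 75th-percentile
   intensity of its non-control probes and the whole matrix multiplied by
   the geometric mean of those quantiles, so every sample's 75th
   percentile ends identical while the overall magnitude stays near the
   raw scale (keeping the downstream baseline subtraction meaningful).

All three maps are strictly increasing per sample, so within-sample probe
rank order is preserved end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .config import PipelineConfig
from .io import SignalMatrix

__all__ = [
    "NormalizationError",
    "SpikeCurve",
    "anchor_normalize",
    "fit_spike_curve",
    "interpolate_to_concentration",
    "percentile_normalize",
    "normalize",
    "SpikeInNormalization",
    "NormalizationResult",
]

log = logging.getLogger(__name__)

#: minimal separation imposed between repaired, exactly-equal knot signals
_KNOT_EPS = 1e-9


class NormalizationError(ValueError):
    """A normalization pre-condition failed; the message names the sample."""


# ---------------------------------------------------------------------------
# stage 1: anchoring
# ---------------------------------------------------------------------------

def _anchor_log_signal(m: SignalMatrix, ann: pd.DataFrame, anchor: str) -> pd.Series:
    """Per-sample mean log10 signal of the anchor spike's probe(s)."""
    probes = [p for p in m.probe_ids
              if p in ann.index and ann.at[p, "is_spike"]
              and ann.at[p, "spike_name"] == anchor]
    if not probes:
        raise NormalizationError(f"anchor spike {anchor!r} has no probes in the matrix")
    sub = m.values.loc[probes]
    zero = (sub <= 0).any(axis=0)
    if zero.any():
        bad = zero.index[zero].tolist()
        raise NormalizationError(
            f"anchor spike {anchor!r} has non-positive signal in sample(s) {bad}"
        )
    return np.log10(sub).mean(axis=0)


def anchor_normalize(
    m: SignalMatrix, ann: pd.DataFrame, cfg: PipelineConfig | None = None
) -> SignalMatrix:
    """Shift each sample's log10 signals so the anchor spike reads
    ``cfg.anchor_log_value`` everywhere.

    The shift is additive in log space (a single multiplicative factor per
    sample), so every within-sample ratio is preserved exactly.
    """
    cfg = cfg or PipelineConfig()
    anchor_log = _anchor_log_signal(m, ann, cfg.anchor_spike_name)
    shifts = cfg.anchor_log_value - anchor_log  # per sample
    factors = np.power(10.0, shifts.to_numpy())
    out = m.values * factors[np.newaxis, :]
    return m.with_values(out)


# ---------------------------------------------------------------------------
# stage 2: spike calibration curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeCurve:
    """Monotone piecewise-linear map log10(signal) -> log10(concentration).

    Knots are one per distinct spike-in (replicate probes averaged on the
    log10 signal scale), sorted by concentration, with non-monotone signal
    sequences repaired by pool-adjacent-violators and exact ties separated
    by a minimal epsilon so the map stays invertible.  Evaluation outside
    the knot range extends the terminal segments linearly.
    """

    sample_id: str
    log_signal: np.ndarray    # knot x-coordinates, strictly increasing
    log_conc: np.ndarray      # knot y-coordinates, strictly increasing

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        xs, ys = self.log_signal, self.log_conc
        x = np.asarray(x, dtype=float)
        out = np.interp(x, xs, ys)
        # linear extension beyond terminal knots
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(x < xs[0], ys[0] + (x - xs[0]) * lo_slope, out)
        out = np.where(x > xs[-1], ys[-1] + (x - xs[-1]) * hi_slope, out)
        return out if out.shape else float(out)

    @property
    def knots(self) -> list[tuple[float, float]]:
        return list(zip(self.log_signal.tolist(), self.log_conc.tolist()))

    def extrapolation_fraction(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(np.mean((x < self.log_signal[0]) | (x > self.log_signal[-1])))


def fit_spike_curve(
    sample: pd.Series, ann: pd.DataFrame, sample_id: str | None = None
) -> SpikeCurve:
    """Fit one sample's calibration curve from its spike-in probes.

    ``sample`` is the sample's linear-scale signal vector indexed by
    probe_id.  Replicate probes of one spike are averaged (arithmetic mean
    of log10 signals); at least two distinct spikes with positive signal
    are required.
    """
    sample_id = sample_id or str(sample.name)
    spikes = ann[ann["is_spike"]]
    present = spikes.index.intersection(sample.index)
    spikes = spikes.loc[present]
    vals = sample.loc[present]
    usable = vals > 0
    spikes, vals = spikes[usable], vals[usable]
    if spikes.empty or spikes["spike_name"].nunique() < 2:
        raise NormalizationError(
            f"sample {sample_id!r}: fewer than 2 usable spike-ins for curve fitting"
        )
    per_spike = (
        pd.DataFrame({
            "log_signal": np.log10(vals.to_numpy(dtype=float)),
            "conc": spikes["spike_log_conc"].to_numpy(dtype=float),
        })
        .groupby("conc", sort=True)["log_signal"]
        .mean()
    )
    conc = per_spike.index.to_numpy()
    sig = per_spike.to_numpy()
    # repair non-monotone signal response (isotonic in concentration order)
    iso = IsotonicRegression(increasing=True)
    sig = iso.fit_transform(conc, sig)
    # separate exact ties so the signal coordinate is strictly increasing
    for i in range(1, len(sig)):
        if sig[i] <= sig[i - 1]:
            sig[i] = sig[i - 1] + _KNOT_EPS
    return SpikeCurve(sample_id=sample_id, log_signal=sig, log_conc=conc)


def interpolate_to_concentration(
    m: SignalMatrix, curves: dict[str, SpikeCurve] | list[SpikeCurve]
) -> SignalMatrix:
    """Map every probe's log10 signal through its sample's spike curve.

    Output is returned on the linear scale (``10**mapped``).  Signals of 0
    map through log10 -> -inf and are floored at the curve's extension of
    zero; in practice zero signals should not survive upstream validation.
    """
    if isinstance(curves, list):
        curves = {c.sample_id: c for c in curves}
    missing = [s for s in m.sample_ids if s not in curves]
    if missing:
        raise NormalizationError(f"no spike curve for sample(s) {missing}")
    out = {}
    tiny = np.finfo(float).tiny
    for s in m.sample_ids:
        x = np.log10(np.maximum(m.values[s].to_numpy(dtype=float), tiny))
        mapped = curves[s](x)
        frac = curves[s].extrapolation_fraction(x)
        if frac > 0:
            log.info("sample %s: %.1f%% of probes outside spike range (extrapolated)",
                     s, 100 * frac)
        out[s] = np.power(10.0, mapped)
    return m.with_values(pd.DataFrame(out, index=m.probe_ids))


# ---------------------------------------------------------------------------
# stage 3: percentile scaling
# ---------------------------------------------------------------------------

def percentile_normalize(
    m: SignalMatrix, ann: pd.DataFrame, cfg: PipelineConfig | None = None
) -> SignalMatrix:
    """Equalize the per-sample 75th percentile over non-control probes.

    Each sample is divided by its own quantile; the whole matrix is then
    multiplied by the geometric mean of the per-sample quantiles so the
    global magnitude is preserved.
    """
    cfg = cfg or PipelineConfig()
    noncontrol = [p for p in m.probe_ids
                  if p not in ann.index or not ann.at[p, "is_control"]]
    if len(noncontrol) < 2:
        raise NormalizationError("fewer than 2 non-control probes for percentile scaling")
    q = m.values.loc[noncontrol].quantile(cfg.percentile / 100.0, interpolation="linear")
    if (q <= 0).any():
        bad = q.index[q <= 0].tolist()
        raise NormalizationError(f"zero {cfg.percentile:g}th percentile in sample(s) {bad}")
    geo = float(np.exp(np.mean(np.log(q.to_numpy(dtype=float)))))
    out = m.values / q * geo
    return m.with_values(out)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def normalize(
    m: SignalMatrix, ann: pd.DataFrame, cfg: PipelineConfig | None = None
) -> SignalMatrix:
    """Anchor, interpolate to the concentration scale, percentile-scale."""
    return SpikeInNormalization(m, ann, cfg).fit().normalized


@dataclass
class NormalizationResult:
    """Outputs of the three-stage normalization.

    Attributes
    ----------
    normalized
        Linear-scale matrix, ``scale="normalized"``.
    curves
        Per-sample fitted :class:`SpikeCurve`.
    shifts
        Per-sample anchoring shift on the log10 scale.
    quantiles
        Per-sample percentile value before the final scaling.
    extrapolation_fraction
        Per-sample fraction of probes mapped outside the spike range.
    """

    normalized: SignalMatrix
    curves: dict[str, SpikeCurve]
    shifts: pd.Series
    quantiles: pd.Series
    extrapolation_fraction: pd.Series

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor_shift_log10": self.shifts,
            "percentile_value": self.quantiles,
            "extrapolation_fraction": self.extrapolation_fraction,
        })

    def summary(self) -> str:
        d = self.diagnostics()
        lines = ["Spike-in normalization", "=" * 52,
                 d.to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def plot_curves(self, ax=None):
        """Plot every sample's calibration curve (log signal vs log conc)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for s, c in self.curves.items():
            ax.plot(c.log_signal, c.log_conc, marker="o", ms=3, label=s)
        ax.set_xlabel("log10 signal")
        ax.set_ylabel("log10 relative concentration")
        ax.legend(fontsize=6)
        return ax


class SpikeInNormalization:
    """Model object for the three-stage spike-in normalization.

    Parameters
    ----------
    matrix
        Raw linear-scale :class:`~rhizotrans.io.SignalMatrix`.
    annotation
        Probe annotation table (validated layout).
    config
        :class:`~rhizotrans.config.PipelineConfig`; defaults reproduce the
        published settings (anchor ``E1A_r60_a20`` at 3.83, 75th percentile).
    """

    def __init__(self, matrix: SignalMatrix, annotation: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.matrix = matrix
        self.annotation = annotation
        self.config = config or PipelineConfig()

    def fit(self) -> NormalizationResult:
        m, ann, cfg = self.matrix, self.annotation, self.config
        anchor_log = _anchor_log_signal(m, ann, cfg.anchor_spike_name)
        shifts = cfg.anchor_log_value - anchor_log
        anchored = anchor_normalize(m, ann, cfg)
        curves = {s: fit_spike_curve(anchored.values[s], ann, s) for s in m.sample_ids}
        mapped = interpolate_to_concentration(anchored, curves)
        tiny = np.finfo(float).tiny
        extrap = pd.Series({
            s: curves[s].extrapolation_fraction(
                np.log10(np.maximum(anchored.values[s].to_numpy(dtype=float), tiny)))
            for s in m.sample_ids})
        noncontrol = [p for p in m.probe_ids
                      if p not in ann.index or not ann.at[p, "is_control"]]
        quantiles = mapped.values.loc[noncontrol].quantile(
            cfg.percentile / 100.0, interpolation="linear")
        scaled = percentile_normalize(mapped, ann, cfg)
        normalized = SignalMatrix(scaled.values, m.conditions.copy(), scale="normalized")
        return NormalizationResult(
            normalized=normalized, curves=curves, shifts=shifts,
            quantiles=quantiles, extrapolation_fraction=extrap,
        )
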