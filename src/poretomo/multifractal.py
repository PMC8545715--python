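"""Singularity and Rényi spectra of 1D measures by dyadic box counting.

A nonnegative signal of length ``L`` (typically a pore frequency curve) is
normalized to a probability measure and partitioned by dyadic downscaling
into ``2**k`` contiguous equal subintervals of relative size ``eps = 2**-k``
for ``k`` in a scale range.  For each moment order ``q``:

* the generalized dimension ``D_q`` is the slope of ``log sum_i mu_i**q``
  against ``log eps``, divided by ``q - 1`` (entropy form at ``q = 1``);
* the singularity strength ``alpha_q`` is the slope of
  ``sum_i w_i(q) log mu_i`` against ``log eps``, and the dimension
  ``f_q`` the slope of ``sum_i w_i(q) log w_i(q)``, where
  ``w_i(q) = mu_i**q / sum_j mu_j**q`` (direct method of Chhabra & Jensen).

All slopes come from ordinary least squares over the retained scales, with
the slope standard error and the coefficient of determination of the same
fit.  Estimates are accepted only when R² meets a threshold (default 0.9).

Empty bins are excluded from every sum; for ``q < 0`` a scale containing an
empty bin is dropped from that ``q``'s regressions entirely, because
``mu**q`` diverges as ``mu -> 0``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FrequencyCurve
from .errors import (
    DegenerateInputError,
    DescriptorError,
    EstimationError,
    InvalidParameterError,
)

__all__ = [
    "DyadicPartition",
    "MultifractalConfig",
    "RegressionEstimate",
    "MultifractalSpectrum",
    "SpectrumDescriptors",
    "dyadic_measures",
    "partition_sum",
    "chhabra_weights",
    "estimate_alpha_f",
    "estimate_Dq",
    "spectrum_descriptors",
    "run_multifractal",
]

DEFAULT_Q_MIN = -9
DEFAULT_Q_MAX = 9
DEFAULT_K_MIN = 1
DEFAULT_K_MAX = 10
DEFAULT_R2_THRESHOLD = 0.9

#: Minimum number of scales for a slope to be estimable at all.
_MIN_SCALES = 3


@dataclass(frozen=True)
class DyadicPartition:
    """Normalized measure over ``2**k`` contiguous equal-length bins."""

    k: int
    measures: np.ndarray

    def __post_init__(self) -> None:
        measures = np.asarray(self.measures, dtype=np.float64)
        if self.k < 1 or len(measures) != 2**self.k:
            raise InvalidParameterError(
                f"expected 2**{self.k} measures, got {len(measures)}"
            )
        if (measures < 0).any():
            raise InvalidParameterError("measures must be nonnegative")
        if abs(measures.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("measures must sum to 1 within 1e-12")
        object.__setattr__(self, "measures", measures)

    @property
    def n_bins(self) -> int:
        return 2**self.k

    @property
    def epsilon(self) -> float:
        """Relative bin size 2**-k."""
        return 2.0**-self.k

    @property
    def has_empty_bins(self) -> bool:
        return bool((self.measures == 0).any())


@dataclass(frozen=True)
class MultifractalConfig:
    """Moment orders, scale range and acceptance threshold."""

    q_min: int = DEFAULT_Q_MIN
    q_max: int = DEFAULT_Q_MAX
    q_step: int = 1
    k_min: int = DEFAULT_K_MIN
    k_max: int = DEFAULT_K_MAX
    r2_threshold: float = DEFAULT_R2_THRESHOLD

    def __post_init__(self) -> None:
        if self.q_min > self.q_max or self.q_step < 1:
            raise InvalidParameterError("invalid q grid")
        if self.k_min < 1 or self.k_min > self.k_max:
            raise InvalidParameterError("invalid k range")
        if not 0 < self.r2_threshold <= 1:
            raise InvalidParameterError("r2_threshold must be in (0, 1]")

    @property
    def q_values(self) -> np.ndarray:
        return np.arange(self.q_min, self.q_max + 1, self.q_step, dtype=float)


@dataclass(frozen=True)
class RegressionEstimate:
    """A slope-based estimate with its OLS standard error and R²."""

    value: float
    se: float
    r2: float
    n_scales: int
    accepted: bool


def _as_signal(curve) -> np.ndarray:
    if isinstance(curve, FrequencyCurve):
        signal = curve.counts.astype(np.float64)
    else:
        signal = np.asarray(curve, dtype=np.float64)
    if signal.ndim != 1:
        raise InvalidParameterError("signal must be 1D")
    if (signal < 0).any():
        raise InvalidParameterError("signal must be nonnegative")
    return signal


def dyadic_measures(curve, k: int) -> DyadicPartition:
    """Aggregate a signal into ``2**k`` contiguous bins and normalize.

    The signal length must be divisible by ``2**k`` so that bins have
    equal length.
    """
    signal = _as_signal(curve)
    n_bins = 2**k
    length = len(signal)
    if k < 1 or n_bins > length:
        raise InvalidParameterError(f"need 2**k <= L, got k={k}, L={length}")
    if length % n_bins:
        raise InvalidParameterError(
            f"signal length {length} not divisible into 2**{k} equal bins"
        )
    total = signal.sum()
    if total <= 0:
        raise DegenerateInputError("signal has zero total mass")
    sums = signal.reshape(n_bins, length // n_bins).sum(axis=1)
    return DyadicPartition(k=k, measures=sums / total)


def partition_sum(partition: DyadicPartition, q: float) -> float:
    """Moment sum ``sum_i mu_i**q`` over non-empty bins (bin count at q=0)."""
    mu = partition.measures[partition.measures > 0]
    return float(np.sum(mu**q))


def chhabra_weights(partition: DyadicPartition, q: float) -> np.ndarray:
    """Normalized moment weights ``mu_i**q / sum_j mu_j**q``.

    Empty bins keep weight 0.  At ``q = 1`` this is the measure itself.
    """
    mu = partition.measures
    out = np.zeros_like(mu)
    nonempty = mu > 0
    powered = mu[nonempty] ** q
    out[nonempty] = powered / powered.sum()
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope SE and R² of an OLS line fit."""
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # y exactly constant: a horizontal line is a perfect fit
        return float(res.slope), float(res.stderr), 1.0
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def _usable_partitions(
    signal: np.ndarray, q: float, k_range: range
) -> tuple[list[DyadicPartition], list[int]]:
    """Partitions retained for a given q (drop empty-bin scales when q < 0)."""
    partitions, ks = [], []
    for k in k_range:
        part = dyadic_measures(signal, k)
        if q < 0 and part.has_empty_bins:
            continue
        partitions.append(part)
        ks.append(k)
    return partitions, ks


def _check_k_range(signal: np.ndarray, k_range: range) -> None:
    if len(k_range) < _MIN_SCALES:
        raise EstimationError(
            f"need at least {_MIN_SCALES} scales, k range has {len(k_range)}"
        )
    if k_range.start < 1 or 2 ** (max(k_range)) > len(signal):
        raise InvalidParameterError(
            f"k range {k_range} not within [1, log2(L={len(signal)})]"
        )


@dataclass(frozen=True)
class AlphaFEstimate:
    alpha: RegressionEstimate
    f: RegressionEstimate
    accepted: bool


def _rejected(n_scales: int = 0) -> RegressionEstimate:
    return RegressionEstimate(
        value=float("nan"), se=float("nan"), r2=float("nan"),
        n_scales=n_scales, accepted=False,
    )


def estimate_alpha_f(
    curve,
    q: float,
    k_range: range | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> AlphaFEstimate:
    """Estimate the singularity strength ``alpha_q`` and dimension ``f_q``.

    ``alpha_q`` is the OLS slope of ``sum_i w_i(q) log mu_i`` versus
    ``log eps`` and ``f_q`` the slope of ``sum_i w_i(q) log w_i(q)``; the
    pair is accepted only if both R² values reach ``r2_threshold``.
    """
    signal = _as_signal(curve)
    if k_range is None:
        k_range = range(DEFAULT_K_MIN, min(DEFAULT_K_MAX, int(np.log2(len(signal)))) + 1)
    _check_k_range(signal, k_range)
    partitions, ks = _usable_partitions(signal, q, k_range)
    if len(ks) < _MIN_SCALES:
        return AlphaFEstimate(alpha=_rejected(len(ks)), f=_rejected(len(ks)), accepted=False)
    x = -np.array(ks, dtype=float) * np.log(2.0)  # log eps
    y_alpha = np.empty(len(ks))
    y_f = np.empty(len(ks))
    for i, part in enumerate(partitions):
        mu = part.measures[part.measures > 0]
        w = chhabra_weights(part, q)
        w = w[w > 0]
        y_alpha[i] = np.sum(w * np.log(mu))
        y_f[i] = np.sum(w * np.log(w))
    a_slope, a_se, a_r2 = _ols(x, y_alpha)
    f_slope, f_se, f_r2 = _ols(x, y_f)
    a_ok = a_r2 >= r2_threshold
    f_ok = f_r2 >= r2_threshold
    return AlphaFEstimate(
        alpha=RegressionEstimate(a_slope, a_se, a_r2, len(ks), a_ok),
        f=RegressionEstimate(f_slope, f_se, f_r2, len(ks), f_ok),
        accepted=a_ok and f_ok,
    )


def estimate_Dq(
    curve,
    q: float,
    k_range: range | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> RegressionEstimate:
    """Estimate the generalized (Rényi) dimension ``D_q``.

    For ``q != 1`` the slope of ``log sum_i mu_i**q`` versus ``log eps`` is
    divided by ``q - 1`` and the slope SE scaled by ``1 / |q - 1|``; at
    ``q = 1`` the entropy form (slope of ``sum mu log mu``) is used.
    """
    signal = _as_signal(curve)
    if k_range is None:
        k_range = range(DEFAULT_K_MIN, min(DEFAULT_K_MAX, int(np.log2(len(signal)))) + 1)
    _check_k_range(signal, k_range)
    partitions, ks = _usable_partitions(signal, q, k_range)
    if len(ks) < _MIN_SCALES:
        return _rejected(len(ks))
    x = -np.array(ks, dtype=float) * np.log(2.0)
    if np.isclose(q, 1.0):
        y = np.array(
            [
                np.sum(m * np.log(m))
                for m in ((p.measures[p.measures > 0]) for p in partitions)
            ]
        )
        slope, se, r2 = _ols(x, y)
        value, value_se = slope, se
    else:
        y = np.array([np.log(partition_sum(p, q)) for p in partitions])
        slope, se, r2 = _ols(x, y)
        value = slope / (q - 1.0)
        value_se = se / abs(q - 1.0)
    return RegressionEstimate(value, value_se, r2, len(ks), r2 >= r2_threshold)


@dataclass(frozen=True)
class SpectrumDescriptors:
    """Shape summary of a spectrum, computed from accepted moments only."""

    alpha_0: float
    alpha_min: float
    alpha_max: float
    width: float
    asymmetry: float
    d0: float
    d1: float
    d2: float
    d0_minus_d2: float
    d_qmin_minus_d_qmax: float
    rejected_q: tuple[float, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rejected_q"] = list(self.rejected_q)
        return d


@dataclass(frozen=True)
class MultifractalSpectrum:
    """Per-q spectrum estimates with acceptance flags."""

    q: np.ndarray
    alpha: np.ndarray
    alpha_se: np.ndarray
    alpha_r2: np.ndarray
    f: np.ndarray
    f_se: np.ndarray
    f_r2: np.ndarray
    d: np.ndarray
    d_se: np.ndarray
    d_r2: np.ndarray
    accepted: np.ndarray
    k_min: int
    k_max: int
    r2_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q,
                "alpha": self.alpha,
                "alpha_se": self.alpha_se,
                "alpha_r2": self.alpha_r2,
                "f": self.f,
                "f_se": self.f_se,
                "f_r2": self.f_r2,
                "D": self.d,
                "D_se": self.d_se,
                "D_r2": self.d_r2,
                "accepted": self.accepted,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def descriptors(self) -> SpectrumDescriptors:
        return spectrum_descriptors(self)

    def _at_q(self, array: np.ndarray, q: float) -> float:
        idx = np.flatnonzero(np.isclose(self.q, q))
        if len(idx) != 1 or not self.accepted[idx[0]]:
            return float("nan")
        return float(array[idx[0]])


def spectrum_descriptors(spectrum: MultifractalSpectrum) -> SpectrumDescriptors:
    """Shape descriptors from the accepted part of a spectrum.

    The asymmetry ``A = (alpha_0 - alpha_min) / (alpha_max - alpha_0)`` is
    NaN when the denominator is below 1e-9 (degenerate, near-point spectrum).
    """
    idx0 = np.flatnonzero(np.isclose(spectrum.q, 0.0))
    if len(idx0) != 1:
        raise DescriptorError("q grid must contain q = 0 exactly once")
    if not spectrum.accepted[idx0[0]]:
        raise DescriptorError("q = 0 estimate rejected; descriptors undefined")
    acc = spectrum.accepted.astype(bool)
    alpha_acc = spectrum.alpha[acc]
    alpha_0 = float(spectrum.alpha[idx0[0]])
    alpha_min = float(np.min(alpha_acc))
    alpha_max = float(np.max(alpha_acc))
    denom = alpha_max - alpha_0
    asym = (alpha_0 - alpha_min) / denom if denom >= 1e-9 else float("nan")
    q_acc = spectrum.q[acc]
    d_acc = spectrum.d[acc]
    d0 = float(spectrum.d[idx0[0]])
    d1 = spectrum._at_q(spectrum.d, 1.0)
    d2 = spectrum._at_q(spectrum.d, 2.0)
    return SpectrumDescriptors(
        alpha_0=alpha_0,
        alpha_min=alpha_min,
        alpha_max=alpha_max,
        width=alpha_max - alpha_min,
        asymmetry=asym,
        d0=d0,
        d1=d1,
        d2=d2,
        d0_minus_d2=d0 - d2 if np.isfinite(d2) else float("nan"),
        d_qmin_minus_d_qmax=float(d_acc[np.argmin(q_acc)] - d_acc[np.argmax(q_acc)]),
        rejected_q=tuple(float(v) for v in spectrum.q[~acc]),
    )


def run_multifractal(
    curve, config: MultifractalConfig | None = None
) -> MultifractalSpectrum:
    """Full spectrum of a frequency curve over the configured q grid.

    Curves whose length is not a power of two are truncated to the largest
    centered ``2**m`` window (with a warning); the scale range is capped at
    ``log2`` of the analyzed length.
    """
    if config is None:
        config = MultifractalConfig()
    signal = _as_signal(curve)
    length = len(signal)
    if length < 2:
        raise InvalidParameterError("curve must have at least 2 slices")
    m = int(np.floor(np.log2(length)))
    if 2**m != length:
        start = (length - 2**m) // 2
        warnings.warn(
            f"curve length {length} is not a power of two; analyzing the "
            f"centered window [{start}, {start + 2 ** m})",
            stacklevel=2,
        )
        signal = signal[start : start + 2**m]
    k_range = range(config.k_min, min(config.k_max, m) + 1)
    q_values = config.q_values
    n = len(q_values)
    cols = {
        name: np.full(n, np.nan)
        for name in ("alpha", "alpha_se", "alpha_r2", "f", "f_se", "f_r2", "d", "d_se", "d_r2")
    }
    accepted = np.zeros(n, dtype=bool)
    for i, q in enumerate(q_values):
        af = estimate_alpha_f(signal, q, k_range, config.r2_threshold)
        dq = estimate_Dq(signal, q, k_range, config.r2_threshold)
        cols["alpha"][i], cols["alpha_se"][i], cols["alpha_r2"][i] = (
            af.alpha.value, af.alpha.se, af.alpha.r2,
        )
        cols["f"][i], cols["f_se"][i], cols["f_r2"][i] = af.f.value, af.f.se, af.f.r2
        cols["d"][i], cols["d_se"][i], cols["d_r2"][i] = dq.value, dq.se, dq.r2
        accepted[i] = af.accepted and dq.accepted
    return MultifractalSpectrum(
        q=q_values,
        accepted=accepted,
        k_min=k_range.start,
        k_max=max(k_range),
        r2_threshold=config.r2_threshold,
        **cols,
    )
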