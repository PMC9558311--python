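"""Correlation functions and VCD/IR spectra.

The VCD lineshape is obtained from the cross-correlation of the electric
and magnetic dipole derivatives,

    C(τ) = ⟨ μ̇(0) · ṁ(τ) ⟩ = ⟨ P(0)v(0) · M(τ)a(τ) ⟩,

evaluated two-sided: only the antisymmetric part [C(τ) − C(−τ)]/2
carries chirality, and its sine transform — multiplied by a quantum
correction factor restoring detailed balance on the classical lineshape
— gives the VCD intensity ΔI(ω).  The IR channel is the cosine transform
of the symmetric part of the μ̇ autocorrelation.

Because μ̇ and ṁ are sums over molecules, the spectrum decomposes
exactly into per-molecule intra terms ⟨μ̇_m(0)·ṁ_m(τ)⟩ and pairwise
cross terms, a partition based on physical observables (APT/AAT) rather
than on any wave-function localization.

All intensities are in arbitrary units: positions, signs and relative
magnitudes of bands are the certified outputs.  The overall sign
convention is fixed so that a mode with positive analytic rotational
strength (P·ℓ)·(M_lab·ℓ) in the double-harmonic limit produces a
positive band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.signal

from .evolution import DerivativeSeries
from .units import C2_CM_K, C_CM_FS

__all__ = [
    "CorrelationFunction",
    "SpectrumConfig",
    "Spectrum",
    "cross_correlation",
    "average_replicas",
    "quantum_correction",
    "vcd_spectrum",
    "ir_spectrum",
    "decompose_spectrum",
    "pair_correlations",
    "spectrum_from_pair_cfs",
    "band_integral",
]


@dataclass
class CorrelationFunction:
    """Two-sided time correlation on a uniform lag grid −t_max..t_max."""

    lags: np.ndarray  # fs
    values: np.ndarray
    n_origins: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags/values shape mismatch")
        if self.lags.size % 2 != 1:
            raise ValueError("lag grid must be symmetric about τ=0")
        steps = np.diff(self.lags)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("lag grid must be uniform")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite correlation values")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])

    @property
    def n_lags(self) -> int:
        """Number of non-negative lags."""
        return self.lags.size // 2 + 1


@dataclass
class SpectrumConfig:
    """Transform parameters.

    ``t_max`` (fs) truncates the correlation; ``window`` ∈ {none, hann}
    applies a Hann taper over [0, t_max]; ``zero_padding`` multiplies the
    transform length (finer frequency grid); ``correction`` selects the
    quantum correction factor: ``harmonic_qcf`` is the dimensionless
    harmonic form βℏω/(1−exp(−βℏω)), ``printed_qcf`` the βℏ/(1−exp(−βℏω))
    variant, ``none`` disables it.
    """

    temperature: float = 300.0
    t_max: float = 2000.0
    window: str = "hann"
    zero_padding: int = 4
    correction: str = "harmonic_qcf"
    volume: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.window not in ("none", "hann"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.correction not in ("harmonic_qcf", "printed_qcf", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.zero_padding < 1:
            raise ValueError("zero_padding must be ≥ 1")


@dataclass
class Spectrum:
    """Frequency grid (cm⁻¹) with total and decomposed intensities."""

    frequencies: np.ndarray
    total: np.ndarray
    intra: dict[int, np.ndarray] = field(default_factory=dict)
    cross: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    channel: str = "vcd"


def cross_correlation(
    a: np.ndarray,
    b: np.ndarray,
    dt: float,
    t_max: float,
) -> CorrelationFunction:
    """Time-origin averaged C(τ) = ⟨a(t)·b(t+τ)⟩ for τ ∈ [−t_max, t_max].

    ``a`` and ``b`` are time series of 3-vectors (or scalars), already
    mean-free, on the same frame support.  FFT-based evaluation with
    explicit per-lag normalization by the overlap count.
    """
    a = np.atleast_2d(np.asarray(a, float).reshape(len(a), -1))
    b = np.atleast_2d(np.asarray(b, float).reshape(len(b), -1))
    if a.shape != b.shape:
        raise ValueError("series must share frame support and dimensionality")
    n = a.shape[0]
    L = int(round(t_max / dt))
    if L >= n:
        raise ValueError(
            f"t_max = {t_max} fs needs {L} lags but only {n} frames are available"
        )
    full = np.zeros(2 * n - 1)
    for k in range(a.shape[1]):
        full += scipy.signal.correlate(b[:, k], a[:, k], mode="full", method="fft")
    # index (n-1)+τ holds Σ_t a(t)·b(t+τ)
    taus = np.arange(-L, L + 1)
    vals = full[(n - 1) + taus] / (n - np.abs(taus))
    return CorrelationFunction(lags=taus * dt, values=vals, n_origins=n)


def average_replicas(cfs: Sequence[CorrelationFunction]) -> CorrelationFunction:
    """Pointwise average of replica correlation functions, weighted by
    the number of time origins each contributes."""
    if not cfs:
        raise ValueError("no correlation functions to average")
    lags = cfs[0].lags
    for cf in cfs[1:]:
        if cf.lags.shape != lags.shape or not np.allclose(cf.lags, lags):
            raise ValueError("replica correlation functions have mismatched lag grids")
    wts = np.array([cf.n_origins for cf in cfs], float)
    vals = np.einsum("r,rl->l", wts, np.stack([cf.values for cf in cfs])) / wts.sum()
    return CorrelationFunction(lags=lags, values=vals, n_origins=int(wts.sum()))


def quantum_correction(
    nu_cm: np.ndarray, temperature: float, kind: str = "harmonic_qcf"
) -> np.ndarray:
    """Quantum correction factor on a wavenumber grid (cm⁻¹).

    ``harmonic_qcf``: βℏω/(1−exp(−βℏω)) — dimensionless, → 1 as ω → 0 and
    → βℏω in the deep quantum limit.  ``printed_qcf``: βℏ/(1−exp(−βℏω))
    (here in units of cm, the constant βℏ being absorbed into the
    arbitrary intensity scale).
    """
    nu = np.asarray(nu_cm, float)
    x = C2_CM_K * nu / temperature  # βℏω, dimensionless
    if kind == "none":
        return np.ones_like(nu)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = -np.expm1(-x)
        if kind == "harmonic_qcf":
            out = np.where(x < 1e-12, 1.0, x / np.where(denom == 0, 1.0, denom))
        elif kind == "printed_qcf":
            # diverges as 1/βℏω at the DC bin; regularized to 1 there
            out = np.where(x < 1e-12, 1.0, 1.0 / np.where(denom == 0, 1.0, denom))
        else:
            raise ValueError(f"unknown correction {kind!r}")
    return out


def _prepare_onesided(cf: CorrelationFunction, cfg: SpectrumConfig, part: str):
    """Windowed one-sided symmetric/antisymmetric part and transform size."""
    L = cf.n_lags - 1
    Lmax = int(round(cfg.t_max / cf.dt))
    if Lmax > L:
        raise ValueError(
            f"t_max = {cfg.t_max} fs exceeds the correlation range {cf.lags[-1]} fs"
        )
    c0 = cf.values[L:]  # τ ≥ 0
    cneg = cf.values[L::-1]  # τ ≤ 0 reversed
    y = 0.5 * (c0 - cneg) if part == "anti" else 0.5 * (c0 + cneg)
    y = y[: Lmax + 1].copy()
    if cfg.window == "hann":
        j = np.arange(Lmax + 1)
        y *= 0.5 * (1.0 + np.cos(np.pi * j / Lmax))
    N = scipy.fft.next_fast_len(cfg.zero_padding * (Lmax + 1))
    return y, N


def _freq_grid(N: int, dt: float) -> np.ndarray:
    return np.arange(N // 2 + 1) / (N * dt) / C_CM_FS


def _sine_transform(cf: CorrelationFunction, cfg: SpectrumConfig) -> tuple[np.ndarray, np.ndarray]:
    y, N = _prepare_onesided(cf, cfg, "anti")
    ft = scipy.fft.rfft(y, N)
    # Σ_j y_j sin(ω t_j) = −Im rfft; VCD sign fixed by the harmonic oracle
    intens = 2.0 * cf.dt * ft.imag
    return _freq_grid(N, cf.dt), intens


def _cosine_transform(cf: CorrelationFunction, cfg: SpectrumConfig) -> tuple[np.ndarray, np.ndarray]:
    y, N = _prepare_onesided(cf, cfg, "sym")
    ft = scipy.fft.rfft(y, N)
    intens = cf.dt * (2.0 * ft.real - y[0])
    return _freq_grid(N, cf.dt), intens


def vcd_spectrum(cf: CorrelationFunction, cfg: SpectrumConfig) -> Spectrum:
    """VCD intensity: QCF × sine transform of the antisymmetric part of
    the ⟨μ̇(0)·ṁ(τ)⟩ correlation (total channel only)."""
    freq, intens = _sine_transform(cf, cfg)
    intens = intens * quantum_correction(freq, cfg.temperature, cfg.correction)
    return Spectrum(frequencies=freq, total=intens, channel="vcd")


def ir_spectrum(cf: CorrelationFunction, cfg: SpectrumConfig) -> Spectrum:
    """IR intensity: QCF × cosine transform of the symmetric part of the
    ⟨μ̇(0)·μ̇(τ)⟩ autocorrelation."""
    freq, intens = _cosine_transform(cf, cfg)
    intens = intens * quantum_correction(freq, cfg.temperature, cfg.correction)
    return Spectrum(frequencies=freq, total=intens, channel="ir")


def pair_correlations(
    series: DerivativeSeries, t_max: float
) -> dict[tuple[int, int], CorrelationFunction]:
    """⟨μ̇_m(0)·ṁ_n(τ)⟩ for every ordered molecule pair (m, n)."""
    out = {}
    for m in range(series.n_molecules):
        for n in range(series.n_molecules):
            out[(m, n)] = cross_correlation(
                series.mu_dot[:, m], series.m_dot[:, n], series.dt, t_max
            )
    return out


def spectrum_from_pair_cfs(
    pair_cfs: dict[tuple[int, int], CorrelationFunction],
    cfg: SpectrumConfig,
) -> Spectrum:
    """Assemble total/intra/cross VCD spectra from ordered-pair CFs.

    intra_m transforms ⟨μ̇_m·ṁ_m⟩; cross_{m,n} (m < n) the symmetrized
    sum of the (m,n) and (n,m) channels, counted once per unordered pair.
    The total equals Σ intra + Σ cross identically (the transform is
    linear in the correlation function).
    """
    mols = sorted({m for m, _ in pair_cfs})
    freq = None
    intra: dict[int, np.ndarray] = {}
    cross: dict[tuple[int, int], np.ndarray] = {}
    total = None
    for m in mols:
        f, s = _sine_transform(pair_cfs[(m, m)], cfg)
        freq = f if freq is None else freq
        intra[m] = s
        total = s.copy() if total is None else total + s
    for i, m in enumerate(mols):
        for n in mols[i + 1 :]:
            summed = CorrelationFunction(
                lags=pair_cfs[(m, n)].lags,
                values=pair_cfs[(m, n)].values + pair_cfs[(n, m)].values,
                n_origins=pair_cfs[(m, n)].n_origins,
            )
            _f, s = _sine_transform(summed, cfg)
            cross[(m, n)] = s
            total = total + s
    qcf = quantum_correction(freq, cfg.temperature, cfg.correction)
    return Spectrum(
        frequencies=freq,
        total=total * qcf,
        intra={m: v * qcf for m, v in intra.items()},
        cross={p: v * qcf for p, v in cross.items()},
        channel="vcd",
    )


def decompose_spectrum(series: DerivativeSeries, cfg: SpectrumConfig) -> Spectrum:
    """Total + intra + cross VCD spectra from a per-molecule derivative
    series (single replica)."""
    return spectrum_from_pair_cfs(pair_correlations(series, cfg.t_max), cfg)


def band_integral(
    spectrum: np.ndarray, frequencies: np.ndarray, lo: float, hi: float
) -> float:
    """Signed integral of an intensity channel over [lo, hi] cm⁻¹."""
    sel = (frequencies >= lo) & (frequencies <= hi)
    return float(np.trapezoid(spectrum[sel], frequencies[sel]))
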