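"""Synthetic NIR-like spectra with controllable class structure.

Each spectrum is a shared absorption envelope (Gaussian peaks near 4004,
4313, 4727 and 5163 cm^-1 on a 12000 -> 3499 cm^-1 grid) plus a linear
combination of smooth orthonormal latent directions, a slow per-sample
baseline drift and white noise.  The latent directions have a fixed
descending variance schedule, so their PCA rank order is known by
construction, and the class signal lives only on designated variance
ranks — including low-variance ones, so "less informative" principal
components can be the class-discriminative ones.

Class signal uses a pairwise-contrast design: each informative latent
component carries a mean contrast between one pair of classes, so every
informative component is needed to tell one class pair apart.  With
unequal class frequencies such contrasts would normally couple the
informative components through the between-class covariance, rotating
the population principal axes away from the latent directions; here that
off-diagonal between-class covariance is cancelled exactly by a shared
(class-independent) correlation of the within-class noise, keeping the
population covariance diagonal in the latent basis.  Non-informative
components are pure noise with respect to the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datasets import SpectraSet

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "inject_outlier", "preset"]

_DEFAULT_PEAKS = (
    (4004.0, 60.0, 0.55),
    (4313.0, 70.0, 0.45),
    (4727.0, 85.0, 0.40),
    (5163.0, 95.0, 0.35),
)

# floor on the smallest eigenvalue of the compensated within-class
# covariance; caps how much mean separation the design can carry
_MIN_WITHIN_EIG = 0.15


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the four-region tobacco set.

    n_per_class mirrors the published class counts (38/144/70/80, total
    332); the grid is 2084 points descending from 12000 to 3499 cm^-1.
    `informative_ranks` are 1-based variance ranks of the latent
    components that carry class signal; `effect_size` sets the mean
    separation of each component's class pair to ``0.5 * effect_size``
    within-class standard deviations (automatically shrunk if the
    compensating within-class covariance would lose positive
    definiteness).  ``effect_size = 0`` plants no signal.
    """

    n_per_class: tuple = (38, 144, 70, 80)
    wavenumber_start: float = 12000.0
    wavenumber_end: float = 3499.0
    n_points: int = 2084
    base_peaks: tuple = _DEFAULT_PEAKS
    envelope_offset: float = 1.2
    n_latent: int = 12
    variance_scale: float = 2.0
    variance_decay: float = 0.65
    informative_ranks: tuple = (1, 6, 7, 8, 10, 11)
    effect_size: float = 3.0
    noise_sd: float = 0.002
    baseline_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class):
            raise ValueError("class counts must be positive")
        if self.n_points < 8:
            raise ValueError("n_points too small")
        if self.n_latent > self.n_points:
            raise ValueError("cannot orthogonalize more latent directions than points")
        lo = min(self.wavenumber_start, self.wavenumber_end)
        hi = max(self.wavenumber_start, self.wavenumber_end)
        for center, _, _ in self.base_peaks:
            if not lo <= center <= hi:
                raise ValueError(f"peak center {center} outside the wavenumber grid")
        ranks = set(self.informative_ranks)
        if not ranks <= set(range(1, self.n_latent + 1)):
            raise ValueError("informative_ranks must lie in 1..n_latent")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_class))

    @property
    def latent_variances(self) -> np.ndarray:
        """Total (within + between class) variance of each latent component."""
        j = np.arange(self.n_latent)
        return self.variance_scale * self.variance_decay**j


@dataclass
class GroundTruth:
    """What the generator actually planted (for oracles and tests)."""

    directions: np.ndarray        # (n_latent, P) orthonormal rows
    variances: np.ndarray         # (n_latent,) planted total variances
    informative_ranks: tuple      # 1-based
    class_offsets: np.ndarray     # (n_classes, n_latent), scaled mean offsets
    within_covariance: np.ndarray  # (n_latent, n_latent), scaled within-class cov
    latent_scores: np.ndarray     # (N, n_latent)
    envelope: np.ndarray = field(default=None)  # type: ignore[assignment]


def _smooth_directions(cfg: SyntheticConfig, wn: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Orthonormal smooth random curves (Gaussian-bump mixtures + Gram-Schmidt)."""
    lo, hi = wn.min(), wn.max()
    curves = np.zeros((cfg.n_latent, wn.size))
    for j in range(cfg.n_latent):
        for _ in range(6):
            center = rng.uniform(lo, hi)
            width = rng.uniform(400.0, 1500.0)
            amp = rng.standard_normal()
            curves[j] += amp * np.exp(-((wn - center) ** 2) / (2 * width**2))
    # Gram-Schmidt; smooth random curves are linearly independent w.p. 1
    for j in range(cfg.n_latent):
        for i in range(j):
            curves[j] -= (curves[j] @ curves[i]) * curves[i]
        norm = np.linalg.norm(curves[j])
        if norm < 1e-10:
            raise ValueError("degenerate latent direction; change the seed")
        curves[j] /= norm
    return curves


def _plan_signal(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Class-mean offsets and the compensating within-class covariance.

    Informative components are matched to class pairs in lexicographic
    order (for 4 classes: (1,2), (1,3), (1,4), (2,3), (2,4), (3,4)); the
    paired classes get opposite mean offsets on that component.  Columns
    are weighted-centred, and the off-diagonal part of the between-class
    covariance B is subtracted from the (unit-diagonal) within-class
    covariance, so the population covariance is exactly diagonal.  If
    ``I - offdiag(B)`` would lose positive definiteness the offsets are
    shrunk to keep its smallest eigenvalue at a fixed floor.
    """
    q = len(cfg.n_per_class)
    weights = np.asarray(cfg.n_per_class, dtype=float)
    weights /= weights.sum()
    mean_offsets = np.zeros((q, cfg.n_latent))
    if q < 2 or cfg.effect_size == 0 or not cfg.informative_ranks:
        return mean_offsets, np.eye(cfg.n_latent)
    delta = 0.5 * cfg.effect_size
    pairs = list(combinations(range(q), 2))
    dims = [r - 1 for r in sorted(cfg.informative_ranks)]
    for i, d in enumerate(dims):
        a, b = pairs[i % len(pairs)]
        mean_offsets[a, d] += +delta / 2.0
        mean_offsets[b, d] += -delta / 2.0
    mean_offsets -= weights @ mean_offsets

    def offdiag_between(m: np.ndarray) -> np.ndarray:
        between = (m.T * weights) @ m
        return between - np.diag(np.diag(between))

    off = offdiag_between(mean_offsets)
    lam_max = np.linalg.eigvalsh(off).max()
    if lam_max > 1.0 - _MIN_WITHIN_EIG:
        shrink = np.sqrt((1.0 - _MIN_WITHIN_EIG) / lam_max)
        mean_offsets *= shrink
        off = offdiag_between(mean_offsets)
    within_cov = np.eye(cfg.n_latent) - off
    return mean_offsets, within_cov


def generate(cfg: SyntheticConfig) -> tuple[SpectraSet, GroundTruth]:
    """Draw a labeled synthetic dataset plus its ground-truth record.

    The per-component total variance (within-class plus between-class) is
    rescaled to the configured geometric schedule exactly, so the
    population PCA rank order equals the configured order.
    """
    rng = np.random.default_rng(cfg.seed)
    wn = np.linspace(cfg.wavenumber_start, cfg.wavenumber_end, cfg.n_points)
    envelope = np.full(cfg.n_points, cfg.envelope_offset)
    for center, width, amp in cfg.base_peaks:
        envelope += amp * np.exp(-((wn - center) ** 2) / (2 * width**2))
    # gentle instrument-like tilt toward low wavenumbers
    envelope += 0.15 * (wn.max() - wn) / (wn.max() - wn.min())

    directions = _smooth_directions(cfg, wn, rng)
    weights = np.asarray(cfg.n_per_class, dtype=float) / cfg.n_samples
    mean_offsets, within_cov = _plan_signal(cfg)
    between_diag = weights @ mean_offsets**2
    # population covariance is diag(within) + diag(B); rescale to schedule
    total = np.diag(within_cov) + between_diag
    scale = np.sqrt(cfg.latent_variances / total)

    labels = np.concatenate(
        [np.full(n, f"R{c + 1}") for c, n in enumerate(cfg.n_per_class)]
    )
    class_idx = np.concatenate(
        [np.full(n, c) for c, n in enumerate(cfg.n_per_class)]
    )
    chol = np.linalg.cholesky(within_cov)
    eps = rng.standard_normal((cfg.n_samples, cfg.n_latent)) @ chol.T
    z = scale * (eps + mean_offsets[class_idx])

    u = np.linspace(-1.0, 1.0, cfg.n_points)
    coefs = rng.normal(0.0, cfg.baseline_sd, (cfg.n_samples, 3))
    baseline = coefs[:, [0]] + coefs[:, [1]] * u + coefs[:, [2]] * u**2
    noise = rng.normal(0.0, cfg.noise_sd, (cfg.n_samples, cfg.n_points))

    absorbance = envelope + z @ directions + baseline + noise
    ds = SpectraSet(
        wavenumbers=wn,
        absorbance=absorbance,
        labels=labels,
        sample_ids=np.array([f"syn{i:04d}" for i in range(cfg.n_samples)]),
    )
    truth = GroundTruth(
        directions=directions,
        variances=cfg.latent_variances.copy(),
        informative_ranks=tuple(cfg.informative_ranks),
        class_offsets=mean_offsets * scale,
        within_covariance=within_cov * np.outer(scale, scale),
        latent_scores=z,
        envelope=envelope,
    )
    return ds, truth


def inject_outlier(
    ds: SpectraSet, magnitude: float, seed: int = 0
) -> tuple[SpectraSet, int]:
    """Displace one random spectrum on a random contiguous band.

    The displacement is `magnitude` times the per-point standard deviation
    across samples; returns the modified dataset and the injected row
    index.  ``magnitude = 0`` leaves the data unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    n, p = ds.absorbance.shape
    idx = int(rng.integers(n))
    band_len = max(p // 10, 1)
    start = int(rng.integers(0, p - band_len + 1))
    sd = ds.absorbance.std(axis=0, ddof=1)
    sd = np.maximum(sd, sd.mean() * 1e-3)
    new = ds.absorbance.copy()
    new[idx, start:start + band_len] += magnitude * sd[start:start + band_len]
    return ds.with_absorbance(new), idx


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named generator configurations.

    'tobacco-like'  — full-size defaults (N = 332, P = 2084).
    'tobacco-small' — same structure at reduced size for quick runs
                      (N = 60, P = 300).
    """
    if name == "tobacco-like":
        base: dict = {}
    elif name == "tobacco-small":
        base = {"n_per_class": (10, 20, 14, 16), "n_points": 300}
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return SyntheticConfig(seed=seed, **base)
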