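"""Grey relational analysis.

Ranks comparison sequences (physiological factors) against a reference
sequence (reaction time) by grey correlation degree: pointwise absolute
differences after preprocessing, a correlation coefficient built from the
global two-level min/max with a resolution ratio phi, and the averaged
coefficient as the degree.

The literal degree formula in the source material sums n coefficients but
divides by n-1, which makes a perfect match exceed 1; the default here
divides by n (the standard grey relational degree, bounded by 1) and
``degree_denominator="n_minus_1"`` selects the literal variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GreyConfig",
    "GreyResult",
    "normalize",
    "init_transform",
    "grey_degree",
    "select_top_factor",
    "FACTOR_PRIORITY",
]

#: Canonical factor order used to break exact gamma ties: composite ratio
#: indices first (they are the designed fatigue indices), then raw band
#: energies, then cardiac factors.
FACTOR_PRIORITY = [
    "alpha_over_beta",
    "alpha_theta_over_beta",
    "alpha_over_beta_psd",
    "alpha_psd",
    "beta_psd",
    "delta_psd",
    "eeg_psd",
    "heart_rate_bpm",
    "rrsd_s",
]

_PREPROCESS = ("normalize", "init_transform", "both", "none")
_DENOMINATORS = ("n", "n_minus_1")


@dataclass(frozen=True)
class GreyConfig:
    phi: float = 0.5
    preprocess: str = "init_transform"
    degree_denominator: str = "n"

    def __post_init__(self) -> None:
        if not 0 < self.phi <= 1:
            raise ValueError("phi must lie in (0, 1]")
        if self.preprocess not in _PREPROCESS:
            raise ValueError(f"preprocess must be one of {_PREPROCESS}")
        if self.degree_denominator not in _DENOMINATORS:
            raise ValueError(f"degree_denominator must be one of {_DENOMINATORS}")


@dataclass
class GreyResult:
    gamma: dict[str, float]
    xi: dict[str, np.ndarray]
    ranking: list[str] = field(default_factory=list)
    config: GreyConfig = field(default_factory=GreyConfig)


def normalize(seq: Sequence[float]) -> np.ndarray:
    """Min-max rescale to [0, 1]; rejects constant sequences."""
    x = np.asarray(seq, dtype=float)
    if x.size < 2:
        raise ValueError("normalize requires length >= 2")
    rng = x.max() - x.min()
    if rng == 0:
        raise ValueError("cannot normalize a constant sequence (zero range)")
    return (x - x.min()) / rng


def init_transform(seq: Sequence[float]) -> np.ndarray:
    """Divide a sequence by its first element; rejects a zero first element."""
    x = np.asarray(seq, dtype=float)
    if x.size == 0:
        raise ValueError("empty sequence")
    if x[0] == 0:
        raise ValueError("init_transform requires a nonzero first element")
    return x / x[0]


def _preprocess(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "normalize":
        return normalize(x)
    if mode == "init_transform":
        return init_transform(x)
    if mode == "both":
        return init_transform(normalize(x))
    return np.asarray(x, dtype=float)


def grey_degree(
    reference: Sequence[float],
    factors: Mapping[str, Sequence[float]],
    cfg: GreyConfig | None = None,
) -> GreyResult:
    """Grey correlation degree of each factor against the reference.

    All sequences must share length n >= 2. The coefficient uses the global
    minimum and maximum of the difference sequences taken jointly over all
    factors and all positions. When every difference is zero (each factor
    identical to the reference) the coefficients are defined as 1.
    """
    cfg = cfg or GreyConfig()
    if not factors:
        raise ValueError("empty factor set")
    ref = np.asarray(reference, dtype=float)
    n = ref.size
    if n < 2:
        raise ValueError("sequences must have length >= 2")
    for name, seq in factors.items():
        if np.asarray(seq).size != n:
            raise ValueError(f"factor {name!r} length differs from reference")

    ref_p = _preprocess(ref, cfg.preprocess)
    deltas = {
        name: np.abs(ref_p - _preprocess(np.asarray(seq, dtype=float), cfg.preprocess))
        for name, seq in factors.items()
    }
    all_d = np.concatenate(list(deltas.values()))
    d_min, d_max = all_d.min(), all_d.max()

    xi: dict[str, np.ndarray] = {}
    gamma: dict[str, float] = {}
    denom = n if cfg.degree_denominator == "n" else n - 1
    for name, d in deltas.items():
        if d_max == 0:
            coeff = np.ones_like(d)
        else:
            coeff = (d_min + cfg.phi * d_max) / (d + cfg.phi * d_max)
        xi[name] = coeff
        gamma[name] = float(coeff.sum() / denom)

    ranking = sorted(gamma, key=lambda k: (-gamma[k], _priority_index(k, factors)))
    return GreyResult(gamma=gamma, xi=xi, ranking=ranking, config=cfg)


def _priority_index(name: str, factors: Mapping[str, Sequence[float]]) -> int:
    if name in FACTOR_PRIORITY:
        return FACTOR_PRIORITY.index(name)
    return len(FACTOR_PRIORITY) + list(factors).index(name)


def select_top_factor(result: GreyResult) -> str:
    """Factor with the largest correlation degree.

    Exact ties are broken by :data:`FACTOR_PRIORITY` (then input order for
    unknown names), with a warning.
    """
    if not result.gamma:
        raise ValueError("empty result")
    top = result.ranking[0]
    best = result.gamma[top]
    tied = [k for k, v in result.gamma.items() if v == best]
    if len(tied) > 1:
        warnings.warn(
            f"grey degree tie between {tied}; keeping {top!r} (canonical order)",
            stacklevel=2,
        )
    return top
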