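"""Synthetic driving-session generator.

Produces multichannel physiological recordings (EEG, RR-interval series) plus
choice-reaction-time samples and 3-level self-assessment labels, with the
statistical structure the downstream analysis assumes:

* a session splits into three periods (alert / transitional / fatigued), with
  reaction-time samples every ``rt_interval_min`` minutes;
* EEG is a sum of band-limited noise components (delta, theta, alpha, beta)
  whose per-epoch variances are set so the alpha/beta band-power ratio tracks
  a per-level target;
* RR intervals have a fixed mean and a per-level dispersion.

Distributional forms (Gaussian RT noise, Gaussian RR jitter) are stand-ins:
no empirical distribution is available for these quantities, only per-level
means/dispersions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SubjectProfile",
    "SimConfig",
    "Session",
    "default_rt_means",
    "simulate_session",
    "simulate_cohort",
    "write_session",
    "read_session",
]

#: EEG band edges (Hz) used by the generator. Theta's 4-8 Hz range is the
#: standard EEG convention.
GENERATOR_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# Per-level mean reaction times (s) by gender and by age band.
GENDER_RT_MEANS = {
    "male": (1.21, 1.30, 1.40),
    "female": (1.24, 1.35, 1.46),
}
AGE_RT_MEANS = {
    "20-30": (1.21, 1.31, 1.41),
    "over30": (1.25, 1.33, 1.45),
}


@dataclass(frozen=True)
class SubjectProfile:
    gender: str = "male"
    age_group: str = "20-30"

    def __post_init__(self) -> None:
        if self.gender not in GENDER_RT_MEANS:
            raise ValueError(f"gender must be one of {sorted(GENDER_RT_MEANS)}")
        if self.age_group not in AGE_RT_MEANS:
            raise ValueError(f"age_group must be one of {sorted(AGE_RT_MEANS)}")


def default_rt_means(profile: SubjectProfile) -> tuple[float, float, float]:
    """Per-level mean RTs for a profile: average of the gender and age rows."""
    g = GENDER_RT_MEANS[profile.gender]
    a = AGE_RT_MEANS[profile.age_group]
    return tuple((gi + ai) / 2.0 for gi, ai in zip(g, a))


@dataclass
class SimConfig:
    """Parameters of one synthetic driving session.

    ``alpha_beta_by_level`` must be strictly increasing: the alpha/beta ratio
    rises as fatigue accumulates. ``level_rt_means_s`` defaults to the
    profile-specific per-level means (see :func:`default_rt_means`).
    """

    duration_min: float = 240.0
    rt_interval_min: float = 3.0
    eeg_fs: float = 256.0
    period_bounds: tuple[float, float] = (44.0, 188.0)
    profile: SubjectProfile = field(default_factory=SubjectProfile)
    level_rt_means_s: tuple[float, float, float] | None = None
    alpha_beta_by_level: tuple[float, float, float] = (0.8, 1.5, 2.2)
    rrsd_by_level: tuple[float, float, float] = (0.05, 0.055, 0.08)
    rr_mean_s: float = 0.8
    rt_noise_s: float = 0.02
    rt_period1_noise_factor: float = 2.0
    rt_floor_s: float = 0.2
    band_scales: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 1.2, "theta": 0.8, "beta": 1.0}
    )
    eeg_white_noise: float = 0.1
    eeg_gain_drift: float = 0.35
    theta_jitter: float = 0.5
    level2_flip_prob: float = 0.25
    filter_order: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.rt_interval_min <= 0:
            raise ValueError("rt_interval_min must be positive")
        if self.eeg_fs <= 2 * GENERATOR_BANDS["beta"][1]:
            raise ValueError("eeg_fs must exceed twice the top band edge (60 Hz)")
        ab = self.alpha_beta_by_level
        if not (0 < ab[0] < ab[1] < ab[2]):
            raise ValueError("alpha_beta_by_level must be positive and strictly increasing")
        if any(v <= 0 for v in self.rrsd_by_level):
            raise ValueError("rrsd_by_level must be positive")
        if self.rr_mean_s <= 0:
            raise ValueError("rr_mean_s must be positive")
        if self.level_rt_means_s is None:
            self.level_rt_means_s = default_rt_means(self.profile)
        if any(v <= 0 for v in self.level_rt_means_s):
            raise ValueError("level_rt_means_s must be positive")
        if not 0.0 <= self.level2_flip_prob <= 1.0:
            raise ValueError("level2_flip_prob must lie in [0, 1]")


@dataclass
class Session:
    """One simulated driving session.

    ``rt_time_min``, ``rt_s`` and ``level`` are aligned: the self-assessment
    label shares the reaction-time sample's timestamp.
    """

    eeg: np.ndarray
    eeg_fs: float
    rr_intervals_s: np.ndarray
    rt_time_min: np.ndarray
    rt_s: np.ndarray
    level: np.ndarray
    profile: SubjectProfile
    session_id: str = "S000"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rt_time_min) != len(self.rt_s) or len(self.rt_s) != len(self.level):
            raise ValueError("rt samples and labels must share timestamps")
        if not np.all(np.isin(self.level, (1, 2, 3))):
            raise ValueError("levels must lie in {1, 2, 3}")
        if np.any(self.rr_intervals_s <= 0):
            raise ValueError("rr intervals must be positive")


def _block_levels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Level per rt-interval block (piecewise-constant trajectory).

    Period 1 is level 1, period 3 is level 3; period 2 is level 2 with
    stochastic flips back to 1 (transitions need not be monotone).
    """
    n_blocks = int(np.ceil(cfg.duration_min / cfg.rt_interval_min))
    mids = (np.arange(n_blocks) + 0.5) * cfg.rt_interval_min
    p1, p2 = cfg.period_bounds
    levels = np.ones(n_blocks, dtype=int)
    in_p2 = (mids >= p1) & (mids < p2)
    levels[in_p2] = 2
    flips = rng.random(n_blocks) < cfg.level2_flip_prob
    levels[in_p2 & flips] = 1
    levels[mids >= p2] = 3
    return levels


def _level_at(levels: np.ndarray, t_min: np.ndarray | float, cfg: SimConfig) -> np.ndarray:
    idx = np.clip(
        (np.asarray(t_min, dtype=float) / cfg.rt_interval_min).astype(int),
        0,
        len(levels) - 1,
    )
    return levels[idx]


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, order: int = 8
) -> np.ndarray:
    # order 8 keeps cross-band leakage under ~4%, tight enough for the
    # generator's per-level band-power ratio targets
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, rng.standard_normal(n))


def _epoch_normalize(x: np.ndarray, spe: int) -> np.ndarray:
    """Scale each full epoch of ``x`` to unit sample standard deviation."""
    n_full = len(x) // spe
    out = x.copy()
    body = out[: n_full * spe].reshape(n_full, spe)
    sd = body.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    body /= sd
    if len(x) > n_full * spe and n_full > 0:
        # remainder samples reuse the last full epoch's scale
        last_sd = x[(n_full - 1) * spe : n_full * spe].std() or 1.0
        out[n_full * spe :] /= last_sd
    return out


def _synth_eeg(cfg: SimConfig, levels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fs = cfg.eeg_fs
    n = int(round(cfg.duration_min * 60 * fs))
    spe = int(round(60 * fs))  # one-minute epochs drive the gain schedule
    n_epochs = max(n // spe, 1)

    comps = {
        name: _epoch_normalize(_band_noise(rng, n, fs, lo, hi, cfg.filter_order), spe)
        for name, (lo, hi) in GENERATOR_BANDS.items()
    }

    epoch_mid_min = np.arange(n_epochs) + 0.5
    epoch_level = _level_at(levels, epoch_mid_min, cfg)
    ratio = np.asarray(cfg.alpha_beta_by_level)[epoch_level - 1]

    beta_g = cfg.band_scales.get("beta", 1.0)
    gains = {
        "delta": np.full(n_epochs, cfg.band_scales.get("delta", 1.0)),
        "theta": cfg.band_scales.get("theta", 1.0)
        * np.exp(cfg.theta_jitter * rng.standard_normal(n_epochs)),
        "alpha": beta_g * np.sqrt(ratio),
        "beta": np.full(n_epochs, beta_g),
    }
    # slow multiplicative drift shared by every band (electrode/impedance
    # drift); cancels in ratio indices but corrupts raw band powers
    if cfg.eeg_gain_drift > 0:
        walk = np.cumsum(rng.standard_normal(n_epochs)) / np.sqrt(n_epochs)
        drift = np.exp(cfg.eeg_gain_drift * walk)
    else:
        drift = np.ones(n_epochs)

    def per_sample(per_epoch: np.ndarray) -> np.ndarray:
        x = np.repeat(per_epoch, spe)
        if len(x) < n:  # remainder samples reuse the last epoch's gain
            x = np.concatenate([x, np.full(n - len(x), per_epoch[-1])])
        return x[:n]

    eeg = np.zeros(n)
    for name, comp in comps.items():
        eeg += comp * per_sample(gains[name])
    eeg *= per_sample(drift)
    if cfg.eeg_white_noise > 0:
        eeg += cfg.eeg_white_noise * rng.standard_normal(n)
    return eeg


def _synth_rr(cfg: SimConfig, levels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """RR series block by block; per-interval dispersion follows the level."""
    rrsd = np.asarray(cfg.rrsd_by_level)
    chunks: list[np.ndarray] = []
    t = 0.0
    for b, lev in enumerate(levels):
        block_end_s = min((b + 1) * cfg.rt_interval_min, cfg.duration_min) * 60.0
        span = block_end_s - t
        if span <= 0:
            continue
        n_est = int(span / cfg.rr_mean_s * 1.3) + 8
        draw = rng.normal(cfg.rr_mean_s, rrsd[lev - 1], n_est)
        draw = np.clip(draw, 0.2 * cfg.rr_mean_s, None)
        take = np.searchsorted(np.cumsum(draw), span) + 1
        chunk = draw[: min(take, n_est)]
        chunks.append(chunk)
        t += chunk.sum()
    return np.concatenate(chunks)


def simulate_session(cfg: SimConfig, session_id: str = "S000") -> Session:
    """Generate one session; deterministic given ``cfg.rng_seed``."""
    if cfg.duration_min * 60 < 60:
        raise ValueError("duration must cover at least one 60-s epoch")
    rng = np.random.default_rng(cfg.rng_seed)
    levels = _block_levels(cfg, rng)

    eeg = _synth_eeg(cfg, levels, rng)
    rr = _synth_rr(cfg, levels, rng)

    n_rt = int(cfg.duration_min // cfg.rt_interval_min)
    rt_t = (np.arange(1, n_rt + 1)) * cfg.rt_interval_min
    # label each sample with the level of the block it closes
    rt_level = _level_at(levels, rt_t - cfg.rt_interval_min / 2.0, cfg)
    means = np.asarray(cfg.level_rt_means_s)[rt_level - 1]
    noise_sd = np.full(n_rt, cfg.rt_noise_s)
    noise_sd[rt_t <= cfg.period_bounds[0]] *= cfg.rt_period1_noise_factor
    rt = means + rng.standard_normal(n_rt) * noise_sd
    rt = np.maximum(rt, cfg.rt_floor_s)

    return Session(
        eeg=eeg,
        eeg_fs=cfg.eeg_fs,
        rr_intervals_s=rr,
        rt_time_min=rt_t.astype(float),
        rt_s=rt,
        level=rt_level,
        profile=cfg.profile,
        session_id=session_id,
        rng_seed=cfg.rng_seed,
    )


def _rounded_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so counts sum exactly to n."""
    keys = list(mix)
    fracs = np.asarray([mix[k] for k in keys], dtype=float)
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("mix fractions must be nonnegative and sum to 1")
    raw = fracs * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return dict(zip(keys, base.tolist()))


def simulate_cohort(
    n_subjects: int,
    profile_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    base_cfg: SimConfig | None = None,
    age_mix: Mapping[str, float] | None = None,
) -> list[Session]:
    """Simulate ``n_subjects`` independent sessions.

    ``profile_mix`` maps gender to its cohort fraction (default 60% male /
    40% female); ``age_mix`` likewise for age bands (default 50/50). Counts
    are apportioned exactly by largest remainder; per-subject seeds are
    spawned from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    profile_mix = profile_mix or {"male": 0.6, "female": 0.4}
    age_mix = age_mix or {"20-30": 0.5, "over30": 0.5}
    gender_counts = _rounded_counts(n_subjects, profile_mix)
    age_counts = _rounded_counts(n_subjects, age_mix)

    genders = [g for g, c in gender_counts.items() for _ in range(c)]
    ages = [a for a, c in age_counts.items() for _ in range(c)]
    child_seeds = np.random.SeedSequence(seed).spawn(n_subjects)

    base = base_cfg or SimConfig()
    sessions = []
    for i in range(n_subjects):
        profile = SubjectProfile(gender=genders[i], age_group=ages[i])
        sub_seed = int(child_seeds[i].generate_state(1)[0])
        cfg = replace(
            base, profile=profile, level_rt_means_s=None, rng_seed=sub_seed
        )
        sessions.append(simulate_session(cfg, session_id=f"S{i:03d}"))
    return sessions


# ---------------------------------------------------------------------------
# Session directory I/O: eeg.csv, rr.csv, rt.csv, meta.json
# ---------------------------------------------------------------------------

def write_session(session: Session, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    t_s = np.arange(len(session.eeg)) / session.eeg_fs
    pd.DataFrame({"t_s": t_s, "value": session.eeg}).to_csv(d / "eeg.csv", index=False)
    pd.DataFrame({"rr_s": session.rr_intervals_s}).to_csv(d / "rr.csv", index=False)
    pd.DataFrame(
        {"t_min": session.rt_time_min, "rt_s": session.rt_s, "level": session.level}
    ).to_csv(d / "rt.csv", index=False)
    meta = {
        "session_id": session.session_id,
        "gender": session.profile.gender,
        "age_group": session.profile.age_group,
        "eeg_fs": session.eeg_fs,
        "rng_seed": session.rng_seed,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


def read_session(directory: str | Path) -> Session:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    eeg = pd.read_csv(d / "eeg.csv")["value"].to_numpy()
    rr = pd.read_csv(d / "rr.csv")["rr_s"].to_numpy()
    rt = pd.read_csv(d / "rt.csv")
    return Session(
        eeg=eeg,
        eeg_fs=float(meta["eeg_fs"]),
        rr_intervals_s=rr,
        rt_time_min=rt["t_min"].to_numpy(dtype=float),
        rt_s=rt["rt_s"].to_numpy(dtype=float),
        level=rt["level"].to_numpy(dtype=int),
        profile=SubjectProfile(meta["gender"], meta["age_group"]),
        session_id=str(meta["session_id"]),
        rng_seed=int(meta["rng_seed"]),
    )
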