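"""Synthetic wearable-temperature cohorts with planted circadian and
infradian structure.

The generator emulates ring-style distal body temperature: minute-level (or
5-minute) temperature + MET (activity) streams per participant, together with
device-like nightly sleep-summary records.  The planted structure is

    T(t) = baseline + group offset + personal offset
           + circadian_amp * c(t)                (24 h cosine, nadir 03:00)
           + sleep_offset * 1[asleep]
           + wake offset * 1[awake]              (per-category, for effect-size
                                                  calibration)
           + cycle_amp * sin(2*pi*(d - phase)/period) * 1[cyclic]
           + nightly noise (one draw per night) + per-sample noise

where ``d`` is the day index.  The infradian component modulates whole nights
(it shifts the nightly maximum), not individual minutes.  Distal temperature is
higher and less noisy during sleep, so ``sleep_offset > 0`` and
``sleep_noise_sd < wake_noise_sd`` by default.

Two generation paths share participant traits (drawn from a common
per-participant substream):

* :func:`generate_participant` / :func:`generate_cohort` — full minute-level
  streams plus nightly summaries derived from them.
* :func:`generate_nightly_cohort` — a reduced nightly-resolution model for
  studies that consume only nightly summaries (cyclicity, wavelet band power,
  nightly cumulative error).

All randomness flows from ``SimConfig.seed``; per-participant substreams are
derived by stable CRC-32 hashing of the participant id, so any participant can
be regenerated bit-identically in isolation.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

CATEGORIES = ("cyclic_female", "acyclic_female", "male")
_CAT_ABBREV = {"cyclic_female": "cf", "acyclic_female": "af", "male": "m"}

DEFAULT_AGE_BINS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80))

#: Circadian waveform: -cos with nadir at 03:00 (mid-sleep), peak 15:00.
CIRCADIAN_NADIR_HOUR = 3.0
#: Mean of the circadian waveform over a typical 23:00-07:00 sleep window,
#: (-(3/pi)*sin(pi/3)); used by the nightly-resolution path.
CIRC_SLEEP_MEAN = -(3.0 / np.pi) * np.sin(np.pi / 3.0)

# Narrative between-group effect-size targets (Cohen's d vs the male category)
# used to calibrate the default mean offsets.
NARRATIVE_D_SLEEP = {"cyclic_female": 1.40, "acyclic_female": 0.41}
NARRATIVE_D_WAKE = {"cyclic_female": -0.41, "acyclic_female": -0.33}


def offsets_for_effect_sizes(
    d_sleep: Mapping[str, float],
    d_wake: Mapping[str, float],
    between_sd: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Translate target Cohen's d values (female category vs male) into the
    all-day mean offset and the additional wake-only offset per category.

    The male category is the reference (offset 0).  Because Cohen's d here is
    a between-participant statistic, offset = d * between-participant sd.
    """
    mean_off = {"male": 0.0}
    wake_off = {"male": 0.0}
    for cat in ("cyclic_female", "acyclic_female"):
        off = d_sleep.get(cat, 0.0) * between_sd
        mean_off[cat] = off
        wake_off[cat] = d_wake.get(cat, 0.0) * between_sd - off
    return mean_off, wake_off


_DEFAULT_MEAN_OFF, _DEFAULT_WAKE_OFF = offsets_for_effect_sizes(
    NARRATIVE_D_SLEEP, NARRATIVE_D_WAKE, between_sd=0.25
)


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the study design: three categories (cyclic female,
    acyclic female, male) with 105/195/300 members, six age bins spanning
    20-80 years balanced within each sex, 26-32-day cycles of amplitude
    0.3 deg C in cyclic participants, and night-to-night noise of 0.1 deg C.
    """

    n_per_group: Mapping[str, int] | int = field(
        default_factory=lambda: {"cyclic_female": 105, "acyclic_female": 195, "male": 300}
    )
    start_date: str = "2020-01-01"
    n_days: int = 180
    sample_minutes: int = 5
    baseline_temp: float = 34.0          # deg C, wake-time distal baseline
    circadian_amp: float = 0.5           # deg C
    sleep_offset: float = 1.0            # deg C added while asleep
    cycle_period_days: tuple[float, float] = (26.0, 32.0)  # uniform draw
    cycle_amp: float = 0.3               # deg C, nightly infradian amplitude
    wake_noise_sd: float = 0.35          # deg C per sample, awake
    sleep_noise_sd: float = 0.15         # deg C per sample, asleep
    nightly_noise_sd: float = 0.10       # deg C, one draw per night
    between_sd: float = 0.25             # deg C, personal baseline spread
    group_mean_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEAN_OFF)
    )
    group_wake_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WAKE_OFF)
    )
    over50_offset: float = -0.30         # deg C for females aged >= 50
    missing_frac: float = 0.02           # fraction of samples dropped at random
    artifact_rate: float = 0.2           # expected low-MET segments per day
    day_gap_rate: float = 0.005          # probability a whole day is missing
    nap_rate: float = 0.1                # expected extra (nap) summary rows per day
    duplicate_rate: float = 0.002        # fraction of rows duplicated by the "device"
    age_bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS
    seed: int = 0

    # -- validation -------------------------------------------------------
    def counts(self) -> dict[str, int]:
        if isinstance(self.n_per_group, int):
            return {cat: self.n_per_group for cat in CATEGORIES}
        return {cat: int(self.n_per_group.get(cat, 0)) for cat in CATEGORIES}

    def validate(self) -> None:
        counts = self.counts()
        if all(v == 0 for v in counts.values()):
            raise ConfigError("n_per_group: at least one category must be non-empty")
        for cat, v in counts.items():
            if v < 0:
                raise ConfigError(f"n_per_group[{cat}]: must be >= 0, got {v}")
        if self.sample_minutes not in (1, 5):
            raise ConfigError(f"sample_minutes: must be 1 or 5, got {self.sample_minutes}")
        if not (0 <= self.missing_frac < 1):
            raise ConfigError(f"missing_frac: must be in [0, 1), got {self.missing_frac}")
        if self.cycle_amp < 0:
            raise ConfigError(f"cycle_amp: must be >= 0, got {self.cycle_amp}")
        for name in ("wake_noise_sd", "sleep_noise_sd", "nightly_noise_sd", "between_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0, got {getattr(self, name)}")
        lo, hi = self.cycle_period_days
        if not (0 < lo <= hi):
            raise ConfigError(f"cycle_period_days: need 0 < lo <= hi, got {self.cycle_period_days}")
        if self.n_days < 1:
            raise ConfigError(f"n_days: must be >= 1, got {self.n_days}")
        if not self.age_bins:
            raise ConfigError("age_bins: must be non-empty")
        for b in self.age_bins:
            if b[0] >= b[1]:
                raise ConfigError(f"age_bins: bin {b} has lo >= hi")

    # -- (de)serialisation ------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["n_per_group"] = self.counts()
        d["age_bins"] = [list(b) for b in self.age_bins]
        d["cycle_period_days"] = list(self.cycle_period_days)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "age_bins" in d:
            d["age_bins"] = tuple(tuple(b) for b in d["age_bins"])
        if "cycle_period_days" in d:
            d["cycle_period_days"] = tuple(d["cycle_period_days"])
        return cls(**d)


@dataclass
class Participant:
    pid: str
    sex: str                      # "female" | "male"
    age: float
    age_bin: str                  # e.g. "20-29"
    category: str                 # one of CATEGORIES
    truth_cyclic: bool
    truth_period_days: float | None
    truth_phase_days: float | None
    baseline_offset: float = 0.0  # personal deviation from group mean, deg C


def _substream(seed: int, pid: str, stream: int) -> np.random.Generator:
    """Stable per-participant RNG substream (CRC-32 of pid keeps it seedable)."""
    h = zlib.crc32(pid.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h, stream]))


def _age_bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi - 1}"


def make_participants(cfg: SimConfig) -> list[Participant]:
    """Draw the cohort roster: ids, ages balanced across bins within each sex,
    and ground-truth cycle parameters for cyclic participants.

    Personal baseline offsets are centred within each category after drawing,
    so the configured between-group mean contrasts (and hence the configured
    effect sizes) are planted exactly rather than up to the sampling error of
    the nuisance draws."""
    cfg.validate()
    counts = cfg.counts()
    nbins = len(cfg.age_bins)
    roster: list[Participant] = []
    for sex in ("female", "male"):
        if sex == "female":
            cats = (["cyclic_female"] * counts["cyclic_female"]
                    + ["acyclic_female"] * counts["acyclic_female"])
        else:
            cats = ["male"] * counts["male"]
        per_cat_index: dict[str, int] = {}
        for i, cat in enumerate(cats):
            j = per_cat_index.get(cat, 0)
            per_cat_index[cat] = j + 1
            pid = f"{_CAT_ABBREV[cat]}{j:04d}"
            lo, hi = cfg.age_bins[i % nbins]
            rng = _substream(cfg.seed, pid, 0)
            age = float(rng.uniform(lo, hi))
            b_i = float(rng.normal(0.0, cfg.between_sd))
            cyclic = cat == "cyclic_female"
            if cyclic:
                period = float(rng.uniform(*cfg.cycle_period_days))
                phase = float(rng.uniform(0.0, period))
            else:
                period = phase = None
            roster.append(Participant(
                pid=pid, sex=sex, age=age, age_bin=_age_bin_label(lo, hi),
                category=cat, truth_cyclic=cyclic,
                truth_period_days=period, truth_phase_days=phase,
                baseline_offset=b_i,
            ))
    # centre personal offsets within category (see docstring)
    for cat in CATEGORIES:
        members = [p for p in roster if p.category == cat]
        if len(members) > 1:
            mu = float(np.mean([p.baseline_offset for p in members]))
            for p in members:
                p.baseline_offset -= mu
    return roster


def roster_frame(roster: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in roster])


def _mean_offset(cfg: SimConfig, p: Participant) -> float:
    off = float(cfg.group_mean_offsets.get(p.category, 0.0)) + p.baseline_offset
    if p.sex == "female" and p.age >= 50:
        off += cfg.over50_offset
    return off


# ---------------------------------------------------------------------------
# Minute-level path
# ---------------------------------------------------------------------------

def generate_participant(p: Participant, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one participant's minute-level stream and nightly summaries.

    Returns ``(minute_df, nightly_df)``.  ``minute_df`` has columns
    ``pid, timestamp, temperature, met, truth_state, truth_artifact``;
    ``nightly_df`` has one row per sleep episode (main sleeps and naps) with
    ``pid, date, sleep_start, sleep_end, sleep_duration, temp_max,
    temp_trend_dev``.  Deterministic for a fixed ``(cfg.seed, p.pid)``.
    """
    cfg.validate()
    rng = _substream(cfg.seed, p.pid, 1)
    step = cfg.sample_minutes
    spd = 1440 // step
    n = cfg.n_days * spd
    start = pd.Timestamp(cfg.start_date)
    minutes = np.arange(n, dtype=np.int64) * step
    ts = start + pd.to_timedelta(minutes, unit="m")
    day_idx = minutes // 1440
    hours = (minutes % 1440) / 60.0
    circ = -np.cos(2.0 * np.pi * (hours - CIRCADIAN_NADIR_HOUR) / 24.0)

    # --- sleep windows (main sleeps) ------------------------------------
    onset_min = np.clip(rng.normal(23 * 60, 30, cfg.n_days), 21.5 * 60, 24.5 * 60)
    dur_min = rng.uniform(7 * 60, 9 * 60, cfg.n_days)
    sleep = np.zeros(n, dtype=bool)
    night_id = np.full(n, -1, dtype=np.int64)
    windows = []  # (night day, abs start min, abs end min, i0, i1, is_nap)
    for d in range(cfg.n_days):
        s_abs = d * 1440 + onset_min[d]
        e_abs = s_abs + dur_min[d]
        i0 = int(np.ceil(s_abs / step))
        i1 = min(int(np.ceil(e_abs / step)), n)
        if i0 >= n or i1 <= i0:
            continue
        sleep[i0:i1] = True
        night_id[i0:i1] = d
        windows.append((d, s_abs, e_abs, i0, i1, False))

    # --- naps: extra, shorter sleep episodes ----------------------------
    n_naps = rng.poisson(cfg.nap_rate * cfg.n_days)
    for _ in range(int(n_naps)):
        d = int(rng.integers(0, cfg.n_days))
        s_abs = d * 1440 + rng.uniform(10 * 60, 18 * 60)
        e_abs = s_abs + rng.uniform(20, 90)
        i0 = int(np.ceil(s_abs / step))
        i1 = min(int(np.ceil(e_abs / step)), n)
        if i0 >= n or i1 <= i0 or sleep[i0:i1].any():
            continue
        sleep[i0:i1] = True
        windows.append((d, s_abs, e_abs, i0, i1, True))

    # --- temperature signal ---------------------------------------------
    base = np.full(n, cfg.baseline_temp + _mean_offset(cfg, p))
    base += cfg.circadian_amp * circ
    base += np.where(sleep, cfg.sleep_offset,
                     float(cfg.group_wake_offsets.get(p.category, 0.0)))
    if p.truth_cyclic and cfg.cycle_amp > 0:
        base += cfg.cycle_amp * np.sin(
            2.0 * np.pi * (day_idx - p.truth_phase_days) / p.truth_period_days
        )
    nightly_noise = rng.normal(0.0, cfg.nightly_noise_sd, cfg.n_days)
    base += np.where(night_id >= 0, nightly_noise[np.clip(night_id, 0, None)], 0.0)
    noise_sd = np.where(sleep, cfg.sleep_noise_sd, cfg.wake_noise_sd)
    base += rng.normal(0.0, 1.0, n) * noise_sd

    met = np.where(sleep, rng.uniform(0.5, 1.2, n), rng.uniform(0.9, 3.0, n))

    # --- nightly summaries from the artifact-free signal ----------------
    rows = []
    for d, s_abs, e_abs, i0, i1, is_nap in windows:
        seg = base[i0:i1]
        rows.append({
            "pid": p.pid,
            "date": (start + pd.Timedelta(days=d)).normalize(),
            "sleep_start": start + pd.Timedelta(minutes=round(s_abs)),
            "sleep_end": start + pd.Timedelta(minutes=round(e_abs)),
            "sleep_duration": float(e_abs - s_abs),
            "temp_max": float(seg.max()),
            "_night_mean": float(seg.mean()),
        })
    nightly = pd.DataFrame(rows)
    if not nightly.empty:
        main = nightly[nightly["sleep_duration"] >= 6 * 60]
        ref = main["_night_mean"].mean() if len(main) else nightly["_night_mean"].mean()
        nightly["temp_trend_dev"] = nightly["_night_mean"] - ref
        nightly = nightly.drop(columns="_night_mean")

    # --- device artifacts: charging spikes with MET ~ 0 -----------------
    temp_out = base.copy()
    met_out = met.copy()
    artifact = np.zeros(n, dtype=bool)
    n_art = int(rng.poisson(cfg.artifact_rate * cfg.n_days))
    for _ in range(n_art):
        a0 = int(rng.integers(0, n))
        a1 = min(a0 + int(np.ceil(rng.uniform(30, 60) / step)), n)
        artifact[a0:a1] = True
    temp_out[artifact] += 1.0
    met_out[artifact] = 0.0

    df = pd.DataFrame({
        "pid": p.pid,
        "timestamp": ts,
        "temperature": temp_out,
        "met": met_out,
        "truth_state": np.where(sleep, "sleep", "wake"),
        "truth_artifact": artifact,
    })

    # --- missingness: whole-day gaps + sample-wise uniform --------------
    keep = np.ones(n, dtype=bool)
    gap_days = rng.random(cfg.n_days) < cfg.day_gap_rate
    if gap_days.any():
        keep &= ~gap_days[day_idx]
    if cfg.missing_frac > 0:
        keep &= rng.random(n) >= cfg.missing_frac
    df = df[keep]

    # --- device-resent duplicate rows ------------------------------------
    if cfg.duplicate_rate > 0 and len(df):
        n_dup = int(round(cfg.duplicate_rate * len(df)))
        if n_dup:
            dup_rows = df.iloc[rng.integers(0, len(df), n_dup)]
            df = pd.concat([df, dup_rows], ignore_index=True)

    return df.reset_index(drop=True), nightly


def generate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the full cohort at minute resolution.

    Returns ``(roster, minute_frames, nightly)`` where ``roster`` is the
    truth table (one row per participant), ``minute_frames`` maps pid to its
    minute-level stream and ``nightly`` stacks all sleep-summary rows.
    """
    roster = make_participants(cfg)
    frames: dict[str, pd.DataFrame] = {}
    nightly_parts = []
    for p in roster:
        mdf, ndf = generate_participant(p, cfg)
        frames[p.pid] = mdf
        nightly_parts.append(ndf)
    nightly = pd.concat(nightly_parts, ignore_index=True) if nightly_parts else pd.DataFrame()
    return roster_frame(roster), frames, nightly


# ---------------------------------------------------------------------------
# Nightly-resolution path
# ---------------------------------------------------------------------------

def generate_participant_nightly(p: Participant, cfg: SimConfig) -> pd.DataFrame:
    """Reduced model emitting one summary row per night directly.

    The night mean is the minute-model expectation (baseline + offsets +
    sleep offset + sleep-window circadian mean + infradian term) plus the
    per-night noise draw; ``temp_max`` sits a fixed two sleep-noise
    standard deviations above the night mean.  Suitable for analyses that
    consume nightly summaries only.
    """
    cfg.validate()
    rng = _substream(cfg.seed, p.pid, 2)
    start = pd.Timestamp(cfg.start_date)
    d = np.arange(cfg.n_days)
    mean = (cfg.baseline_temp + _mean_offset(cfg, p) + cfg.sleep_offset
            + cfg.circadian_amp * CIRC_SLEEP_MEAN)
    night_mean = np.full(cfg.n_days, mean)
    if p.truth_cyclic and cfg.cycle_amp > 0:
        night_mean = night_mean + cfg.cycle_amp * np.sin(
            2.0 * np.pi * (d - p.truth_phase_days) / p.truth_period_days
        )
    night_mean = night_mean + rng.normal(0.0, cfg.nightly_noise_sd, cfg.n_days)
    onset_min = np.clip(rng.normal(23 * 60, 30, cfg.n_days), 21.5 * 60, 24.5 * 60)
    dur_min = rng.uniform(7 * 60, 9 * 60, cfg.n_days)
    df = pd.DataFrame({
        "pid": p.pid,
        "date": start + pd.to_timedelta(d, unit="D"),
        "sleep_start": start + pd.to_timedelta(np.round(d * 1440 + onset_min), unit="m"),
        "sleep_end": start + pd.to_timedelta(np.round(d * 1440 + onset_min + dur_min), unit="m"),
        "sleep_duration": dur_min,
        "temp_max": night_mean + 2.0 * cfg.sleep_noise_sd,
        "temp_trend_dev": night_mean - night_mean.mean(),
    })
    keep = rng.random(cfg.n_days) >= cfg.day_gap_rate
    return df[keep].reset_index(drop=True)


def generate_nightly_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nightly-resolution cohort: ``(roster, nightly)``."""
    roster = make_participants(cfg)
    nightly = pd.concat(
        [generate_participant_nightly(p, cfg) for p in roster], ignore_index=True
    )
    return roster_frame(roster), nightly


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def write_cohort(cfg: SimConfig, outdir, minute: bool = True) -> None:
    """Write cohort fixtures: per-participant Parquet streams, a roster CSV
    and a nightly-summary Parquet file under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if minute:
        roster, frames, nightly = generate_cohort(cfg)
        raw = out / "raw"
        raw.mkdir(exist_ok=True)
        for pid, df in frames.items():
            df.to_parquet(raw / f"{pid}.parquet", index=False)
    else:
        roster, nightly = generate_nightly_cohort(cfg)
    roster.to_csv(out / "cohort.csv", index=False)
    nightly.to_parquet(out / "nightly.parquet", index=False)
    (out / "sim_config.json").write_text(cfg.to_json())
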