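"""Synthetic display recordings and broods with the structure the analyses assume.

The display generator is a coupled renewal process.  A single driving renewal
train of candidate movement times (gamma or lognormal inter-event times) is
laid down over the analysis window; every candidate movement is expressed on
both flaps.  With probability ``p_sync`` the right-side start is the left
start plus a small jitter drawn uniformly from ±``jitter_frames`` — a
synchronized bilateral movement.  Otherwise the partner's start is displaced
beyond the classifier tolerance, so the candidate contributes one left-only
and one right-only movement.  With jitter no larger than the tolerance the
expected proportion synchronized has the closed form

    E[proportion_sync] = p / (2 - p),        p = p_sync,

since each coupled draw adds one matched pair while each uncoupled draw adds
two one-sided movements; this closed form is used as a test oracle.  The
shared driving train keeps each side's inter-movement interval distribution
equal to the driving distribution, so preset interval means are recovered
per side by the scoring pipeline.

Species presets are loosely calibrated to estimated group mean intervals of
0.21 s (fast, fully synchronized congener), 1.0 s (leech morph) and 3.2 s
(darter morph); dispersion is a free choice because no published estimate
exists — see docs/methods.md.

Broods are drawn offspring-by-offspring under a single-locus dominance model:
a dam gamete from her genotype, a sire gamete from the sire-pool dominant
allele frequency, phenotype by dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .events import (
    DEFAULT_ANALYSIS_LENGTH,
    DEFAULT_ANALYSIS_START,
    DEFAULT_FPS,
    DisplayRecording,
    EventTrack,
    Morph,
    MovementEvent,
    Side,
)
from .polymorphism import BroodCounts, DamGenotype, GeneticModel

IntervalFamily = Literal["gamma", "lognormal"]


@dataclass
class DisplaySimParams:
    """Parameters of one synthetic display recording."""

    interval_mean_s: float = 1.0
    interval_sd_s: float = 0.5
    duration_mean_s: float = 0.4
    duration_sd_s: float = 0.1
    interval_family: IntervalFamily = "gamma"
    duration_family: IntervalFamily = "gamma"
    p_sync: float = 0.6
    jitter_frames: int = 2
    fps: float = DEFAULT_FPS
    analysis_start_frame: int = DEFAULT_ANALYSIS_START
    analysis_length_frames: int = DEFAULT_ANALYSIS_LENGTH
    seed: int = 0
    recording_id: str = "sim"
    species: str = ""
    morph: Morph = Morph.NONE
    water_temp: float | None = None

    def __post_init__(self) -> None:
        for name in ("interval_mean_s", "interval_sd_s",
                     "duration_mean_s", "duration_sd_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_sync <= 1.0:
            raise ValueError("p_sync must be in [0, 1]")
        if self.jitter_frames < 0:
            raise ValueError("jitter_frames must be non-negative")
        if self.interval_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown interval family {self.interval_family!r}")
        if self.duration_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown duration family {self.duration_family!r}")


@dataclass
class BroodSimParams:
    n_offspring: int
    model: GeneticModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 0:
            raise ValueError("n_offspring must be non-negative")


def _draw_positive(
    rng: np.random.Generator, family: str, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from a positive right-skewed family parameterized by mean and SD."""
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=size)
    # lognormal: match mean and SD on the natural scale
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def simulate_display(params: DisplaySimParams) -> DisplayRecording:
    """Generate one recording from the coupled-renewal display model."""
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    lo = params.analysis_start_frame
    hi = lo + params.analysis_length_frames
    mean_frames = params.interval_mean_s * fps

    # Driving renewal train of candidate start frames across the window.  The
    # floor of 2*jitter+1 frames per gap keeps jittered partners in order, so
    # full coupling yields exactly one matchable pair per candidate.
    min_gap = float(max(1, 2 * params.jitter_frames + 1))
    n_guess = max(8, int(2.5 * params.analysis_length_frames / mean_frames) + 8)
    gaps = _draw_positive(
        rng, params.interval_family, params.interval_mean_s, params.interval_sd_s,
        n_guess,
    ) * fps
    gaps = np.maximum(np.round(gaps), min_gap)
    starts = lo + np.cumsum(gaps)
    while starts.size and starts[-1] < hi:
        extra = _draw_positive(
            rng, params.interval_family, params.interval_mean_s,
            params.interval_sd_s, n_guess,
        ) * fps
        extra = np.maximum(np.round(extra), min_gap)
        starts = np.concatenate([starts, starts[-1] + np.cumsum(extra)])
    candidates = starts[starts < hi].astype(int)

    # Partner displacement for uncoupled draws: a narrow band just beyond the
    # jitter plus the classifier-tolerance slack, with a neighbour-safety
    # check, so a displaced partner can neither match its own candidate nor
    # stray into a neighbouring one.
    displace_lo = params.jitter_frames + DEFAULT_TOLERANCE_SLACK
    displace_hi = displace_lo + 4
    safety = displace_hi + params.jitter_frames + DEFAULT_TOLERANCE_SLACK

    left_rows: list[tuple[int, int]] = []
    right_rows: list[tuple[int, int]] = []
    for idx, start in enumerate(candidates):
        dur_l, dur_r = np.maximum(
            np.round(_draw_positive(
                rng, params.duration_family, params.duration_mean_s,
                params.duration_sd_s, 2,
            ) * fps), 1.0).astype(int)
        coupled = rng.random() < params.p_sync
        if coupled:
            offset = int(rng.integers(-params.jitter_frames,
                                      params.jitter_frames + 1))
            l_start, r_start = int(start), int(start) + offset
            if not (lo <= l_start and lo <= r_start
                    and l_start + dur_l < hi and r_start + dur_r < hi):
                continue  # truncate the pair jointly so coupling is exact
            left_rows.append((l_start, l_start + dur_l))
            right_rows.append((r_start, r_start + dur_r))
        else:
            l_start = int(start)
            if lo <= l_start and l_start + dur_l < hi:
                left_rows.append((l_start, l_start + dur_l))
            d = int(rng.integers(displace_lo, displace_hi + 1))
            sign = 1 if rng.random() < 0.5 else -1
            gap_next = (candidates[idx + 1] - start
                        if idx + 1 < len(candidates) else np.inf)
            gap_prev = (start - candidates[idx - 1] if idx > 0 else np.inf)
            if (sign > 0 and gap_next <= safety) and gap_prev > safety:
                sign = -1
            elif (sign < 0 and gap_prev <= safety) and gap_next > safety:
                sign = 1
            if (sign > 0 and gap_next <= safety) or (sign < 0 and gap_prev <= safety):
                continue  # no safe slot for the partner; one-sided draw only
            r_start = int(start) + sign * d
            if lo <= r_start and r_start + dur_r < hi:
                right_rows.append((r_start, r_start + dur_r))

    def build(side: Side, rows: list[tuple[int, int]]) -> EventTrack:
        rows = sorted(rows)
        deduped: list[tuple[int, int]] = []
        for s, e in rows:
            if deduped and s <= deduped[-1][0]:
                continue  # drop chance same-start collisions
            deduped.append((s, e))
        return EventTrack(side, [MovementEvent(side, s, e) for s, e in deduped])

    return DisplayRecording(
        recording_id=params.recording_id,
        left=build(Side.LEFT, left_rows),
        right=build(Side.RIGHT, right_rows),
        species=params.species,
        morph=params.morph,
        water_temp=params.water_temp,
        fps=fps,
        analysis_start_frame=params.analysis_start_frame,
        analysis_length_frames=params.analysis_length_frames,
    )


#: Margin added above the jitter when displacing an uncoupled partner, so the
#: displaced event cannot fall inside the default classifier tolerance.
DEFAULT_TOLERANCE_SLACK = 5


PRESETS: dict[str, dict] = {
    # Fast, metronomic, fully synchronized display (congeneric comparator);
    # durations shortened below the interval so movements rarely overlap.
    "congener": dict(
        interval_mean_s=0.21, interval_sd_s=0.05, p_sync=1.0, jitter_frames=2,
        duration_mean_s=0.12, duration_sd_s=0.03,
        species="L_cardium", morph=Morph.NONE,
    ),
    # Slow, erratic, partly synchronized darter-mimic display.
    "darter_morph": dict(
        interval_mean_s=3.2, interval_sd_s=2.0, p_sync=0.6, jitter_frames=2,
        duration_mean_s=0.4, duration_sd_s=0.1,
        species="L_fasciola", morph=Morph.DARTER,
    ),
    # Intermediate-rate, erratic leech-mimic display.
    "leech_morph": dict(
        interval_mean_s=1.0, interval_sd_s=0.7, p_sync=0.6, jitter_frames=2,
        duration_mean_s=0.3, duration_sd_s=0.08,
        species="L_fasciola", morph=Morph.LEECH,
    ),
}


def species_preset(name: str, seed: int = 0, recording_id: str | None = None,
                   **overrides) -> DisplaySimParams:
    """Generator parameters loosely calibrated to each display group."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return DisplaySimParams(
        seed=seed, recording_id=recording_id or f"{name}_{seed}", **kwargs
    )


def simulate_recording_set(
    n_per_group: dict[str, int],
    seed: int = 0,
    between_recording_cv: float = 0.10,
    **overrides,
) -> tuple[list[DisplayRecording], dict[str, str]]:
    """Simulate a study-like set of recordings across preset groups.

    Real displaying individuals differ in tempo, so each recording's mean
    interval is scaled by a lognormal factor with coefficient of variation
    ``between_recording_cv`` (0 disables this).  Returns the recordings and a
    recording_id → group map.  Per-recording seeds are spawned from ``seed``
    so the set is reproducible as a whole.
    """
    if between_recording_cv < 0:
        raise ValueError("between_recording_cv must be non-negative")
    root = np.random.default_rng(seed)
    recordings, grouping = [], {}
    for group in sorted(n_per_group):
        for i in range(n_per_group[group]):
            child = int(root.integers(0, 2**31 - 1))
            if between_recording_cv > 0:
                sigma2 = math.log(1.0 + between_recording_cv**2)
                tempo = root.lognormal(-sigma2 / 2.0, math.sqrt(sigma2))
            else:
                tempo = 1.0
            rid = f"{group}_{i:02d}"
            params = species_preset(group, seed=child, recording_id=rid, **overrides)
            params.interval_mean_s *= tempo
            params.interval_sd_s *= tempo
            recordings.append(simulate_display(params))
            grouping[rid] = group
    return recordings, grouping


def simulate_brood(params: BroodSimParams) -> BroodCounts:
    """Draw a brood under the single-locus model: one dam and one sire gamete
    per offspring, phenotype by dominance."""
    rng = np.random.default_rng(params.seed)
    model = params.model
    p_dam_dom = {
        DamGenotype.HOMOZYGOUS_DOMINANT: 1.0,
        DamGenotype.HETEROZYGOUS: 0.5,
        DamGenotype.HOMOZYGOUS_RECESSIVE: 0.0,
    }[model.dam_genotype]
    n = params.n_offspring
    dam_dom = rng.random(n) < p_dam_dom
    sire_dom = rng.random(n) < model.sire_dominant_freq
    shows_dominant = dam_dom | sire_dom
    n_dominant = int(shows_dominant.sum())
    counts = {
        model.dominant_morph: n_dominant,
        model.recessive_morph: n - n_dominant,
    }
    return BroodCounts(
        n_darter=counts[Morph.DARTER],
        n_leech=counts[Morph.LEECH],
        dam_morph=model.dam_morph(),
    )


def params_to_dict(params: DisplaySimParams) -> dict:
    """Serialize generator parameters (for YAML configs and provenance logs)."""
    d = asdict(params)
    d["morph"] = params.morph.value
    return d


def params_from_dict(d: dict) -> DisplaySimParams:
    d = dict(d)
    if "morph" in d:
        d["morph"] = Morph(d["morph"])
    return DisplaySimParams(**d)
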