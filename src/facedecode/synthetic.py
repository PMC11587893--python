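"""Synthetic multi-subject evoked-response generator.

Emulates the recording and design structure of a face-perception MEG/EEG
experiment: eight stimulus categories (aggressive/neutral/happy dog and human
faces, household objects, phase-scrambled images), 176 trials per category
(88 color + 88 grayscale), epochs from -200 to 500 ms sampled at 600 Hz, a
sensor array of 204 planar gradiometers (102 pairs) grouped into 12 scalp
regions plus 32 EEG electrodes, and per-subject trait-empathy scores (IRI
subscales) that can modulate how separable chosen category pairs are.

Each simulated trial is ``category template + noise``.  Templates are sums of
Gaussian-windowed half-sine components with the main deflection peaking near
105 ms (the earliest high-amplitude response of evoked face data) and, for
emotional categories, a sustained 200-350 ms component in the latency range of
the early posterior negativity / late posterior positivity.  Noise is Gaussian
AR(1) in time, mixed across neighbouring channels with a variance-preserving
kernel.  Category-pair separability is injected through unit-norm
spatiotemporal patterns whose amplitude equals
``base_effect * max(0, 1 + beta * z_trait)``, i.e. a linear modulation of the
effect size by the standardized trait score, floored at zero.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

log = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "ChannelInfo",
    "SensorLayout",
    "StimulusDesign",
    "SimulationConfig",
    "TraitProfile",
    "EpochsSet",
    "DEFAULT_CATEGORIES",
    "EMOTIONAL_CATEGORIES",
    "DEFAULT_REGIONS",
    "build_layout",
    "make_design",
    "category_templates",
    "pair_separation",
    "simulate_subject",
    "simulate_cohort",
    "uniform_trait_sampler",
    "derive_seed",
]

#: Stimulus category codes: aggressive/neutral/happy dog (AD/ND/HD) and human
#: (AH/NH/HH) faces, household objects (OB), phase-scrambled images (S).
DEFAULT_CATEGORIES = ("AD", "ND", "HD", "AH", "NH", "HH", "OB", "S")

#: Categories carrying an emotional expression; their templates receive an
#: additional sustained 200-350 ms component.
EMOTIONAL_CATEGORIES = ("AD", "HD", "AH", "HH")

#: The 12 gradiometer region groups (left/right x six scalp areas).
DEFAULT_REGIONS = tuple(
    f"{side}-{area}"
    for side in ("left", "right")
    for area in (
        "frontal",
        "central",
        "parieto-occipital",
        "occipital",
        "anterior-temporal",
        "posterior-temporal",
    )
)

#: IRI subscales are 7 items scored 0-4, hence the 0-28 instrument range.
IRI_RANGE = (0.0, 28.0)

TRAIT_NAMES = ("EC", "PT", "FS", "PD", "ani_EC", "ani_PT")


class ConfigurationError(ValueError):
    """An infeasible or inconsistent layout/design/simulation configuration."""


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a child seed (< 2**31) from a master seed, stage name and index.

    Deterministic and stable across processes; used to give every subject,
    permutation and cross-validation split its own reproducible stream.
    """
    h = zlib.crc32(f"{stage}:{index}".encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelInfo:
    """One recording channel: name, modality, planar-pair id, region group."""

    name: str
    modality: str  # "planar_gradiometer" | "eeg"
    pair_id: int | None
    group: str | None


@dataclass
class SensorLayout:
    """Names, modality, planar-pair index and region group for every channel."""

    channels: tuple[ChannelInfo, ...]

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def grad_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.modality == "planar_gradiometer"],
            dtype=int,
        )

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.modality == "eeg"], dtype=int
        )

    @property
    def pairs(self) -> dict[int, tuple[int, int]]:
        """pair_id -> (channel index, channel index), in layout order."""
        out: dict[int, list[int]] = {}
        for i, c in enumerate(self.channels):
            if c.pair_id is not None:
                out.setdefault(c.pair_id, []).append(i)
        return {pid: (idx[0], idx[1]) for pid, idx in out.items()}

    @property
    def groups(self) -> dict[str, list[int]]:
        """region label -> gradiometer channel indices."""
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.channels):
            if c.group is not None:
                out.setdefault(c.group, []).append(i)
        return out

    def modality_indices(self, modality: str) -> np.ndarray:
        if modality == "meg":
            return self.grad_indices
        if modality == "eeg":
            return self.eeg_indices
        raise ValueError(f"unknown modality {modality!r}; expected 'meg' or 'eeg'")

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        pair_members: dict[int, int] = {}
        for c in self.channels:
            if c.name in seen:
                raise ConfigurationError(f"duplicate channel name {c.name!r}")
            seen.add(c.name)
            if c.modality not in ("planar_gradiometer", "eeg"):
                raise ConfigurationError(f"unknown modality {c.modality!r}")
            if c.modality == "planar_gradiometer":
                if c.pair_id is None:
                    raise ConfigurationError(f"gradiometer {c.name!r} lacks a pair id")
                pair_members[c.pair_id] = pair_members.get(c.pair_id, 0) + 1
                if c.group is None:
                    raise ConfigurationError(f"gradiometer {c.name!r} lacks a group")
        for pid, n in pair_members.items():
            if n != 2:
                raise ConfigurationError(f"pair {pid} has {n} members (expected 2)")


def build_layout(
    n_grad_pairs: int = 102,
    n_eeg: int = 32,
    groups: Sequence[str] = DEFAULT_REGIONS,
    group_size_bounds: tuple[int, int] = (12, 20),
) -> SensorLayout:
    """Build a sensor layout of planar-gradiometer pairs partitioned into
    region groups, plus EEG electrodes.

    Pairs are distributed as evenly as possible over the groups (both channels
    of a pair share a group); the defaults give the 204-gradiometer, 12-group
    arrangement with 16-18 channels per group, within the conventional
    12-20-channels-per-group bounds.  Deterministic given its inputs.
    """
    if n_grad_pairs < 0 or n_eeg < 0:
        raise ConfigurationError("channel counts must be non-negative")
    groups = tuple(groups)
    if n_grad_pairs > 0 and not groups:
        raise ConfigurationError("at least one group is required for gradiometers")
    channels: list[ChannelInfo] = []
    if n_grad_pairs:
        base, rem = divmod(n_grad_pairs, len(groups))
        pair_counts = [base + 1] * rem + [base] * (len(groups) - rem)
        lo, hi = group_size_bounds
        for g, npairs in zip(groups, pair_counts):
            size = 2 * npairs
            if not (lo <= size <= hi):
                raise ConfigurationError(
                    f"group {g!r} would contain {size} channels, outside the "
                    f"allowed [{lo}, {hi}] range"
                )
        pid = 0
        for g, npairs in zip(groups, pair_counts):
            for _ in range(npairs):
                for leg in ("a", "b"):
                    channels.append(
                        ChannelInfo(
                            name=f"GRAD{pid:03d}{leg}",
                            modality="planar_gradiometer",
                            pair_id=pid,
                            group=g,
                        )
                    )
                pid += 1
    for i in range(n_eeg):
        channels.append(ChannelInfo(name=f"EEG{i + 1:03d}", modality="eeg", pair_id=None, group=None))
    return SensorLayout(channels=tuple(channels))


# ---------------------------------------------------------------------------
# Stimulus design
# ---------------------------------------------------------------------------


@dataclass
class StimulusDesign:
    """Categories, stimulus sets and trial counts of the experiment."""

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_unique_stimuli: int = 80
    repeats_per_stimulus: tuple[int, int] = (8, 10)
    sets: tuple[str, ...] = ("color", "grayscale")
    trials_per_category_per_set: int = 88
    trials_per_category: int | None = None  # materialized by make_design


def make_design(config: StimulusDesign | None = None) -> StimulusDesign:
    """Validate a stimulus design and materialize per-category trial counts."""
    config = config or StimulusDesign()
    if not config.categories:
        raise ConfigurationError("design must declare at least one category")
    if len(set(config.categories)) != len(config.categories):
        raise ConfigurationError("category codes must be unique")
    if not config.sets:
        raise ConfigurationError("design must declare at least one stimulus set")
    if config.trials_per_category_per_set <= 0:
        raise ConfigurationError("trials_per_category_per_set must be positive")
    total = config.trials_per_category_per_set * len(config.sets)
    return replace(config, trials_per_category=total)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


@dataclass
class TraitProfile:
    """Per-subject trait empathy scores (IRI subscales).

    EC/PT are the emotional-concern and perspective-taking subscales, FS/PD
    fantasy and personal distress; ``ani_`` variants are the animal-directed
    versions.  ``response_times`` optionally maps (question, category) to the
    rating response time in seconds.
    """

    subject_id: str
    EC: float | None = None
    PT: float | None = None
    FS: float | None = None
    PD: float | None = None
    ani_EC: float | None = None
    ani_PT: float | None = None
    response_times: dict[tuple[str, str], float] | None = None

    def score(self, name: str) -> float | None:
        if name not in TRAIT_NAMES:
            raise KeyError(f"unknown trait subscale {name!r}")
        return getattr(self, name)

    def validate(self, bounds: Mapping[str, tuple[float, float]] | None = None) -> None:
        for name in TRAIT_NAMES:
            v = getattr(self, name)
            if v is None:
                continue
            lo, hi = (bounds or {}).get(name, IRI_RANGE)
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"trait {name}={v} of {self.subject_id} outside [{lo}, {hi}]"
                )


def uniform_trait_sampler(
    bounds: tuple[float, float] = IRI_RANGE,
) -> Callable[[np.random.Generator, str], TraitProfile]:
    """Trait sampler drawing every subscale independently and uniformly over
    the instrument range (no distributional claim is made for real cohorts)."""

    lo, hi = bounds

    def sample(rng: np.random.Generator, subject_id: str) -> TraitProfile:
        vals = rng.uniform(lo, hi, size=len(TRAIT_NAMES))
        return TraitProfile(subject_id, **dict(zip(TRAIT_NAMES, vals)))

    return sample


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the evoked-response simulation.

    ``pair_effects`` maps an (ordered) category pair to the dimensionless
    amplitude separation injected between the two templates (the L2 norm of
    the template difference contributed by that pair's pattern).
    ``trait_coupling`` maps a pair to ``(trait_name, beta)``: the realized
    separation is ``base * max(0, 1 + beta * z)`` with ``z`` the trait score
    standardized by the instrument range (uniform-distribution mean and SD).
    """

    sampling_rate: float = 600.0
    epoch_window: tuple[float, float] = (-200.0, 500.0)
    n_subjects: int = 15
    peak_latency_ms: float = 105.0
    base_amplitude: float = 5.0
    category_amplitude: float = 5.0
    pair_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    trait_coupling: Mapping[tuple[str, str], tuple[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    spatial_mixing_width: int = 3
    trait_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    emotional_categories: tuple[str, ...] = EMOTIONAL_CATEGORIES
    pattern_seed: int = 1234

    def validate(self) -> None:
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive and finite")
        t0, t1 = self.epoch_window
        if not (np.isfinite(t0) and np.isfinite(t1) and t0 < 0.0 < t1):
            raise ConfigurationError("epoch_window must satisfy start < 0 < end")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative and finite")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ConfigurationError("ar1_coef must lie in [0, 1)")
        for v in (self.peak_latency_ms, self.base_amplitude, self.category_amplitude):
            if not np.isfinite(v):
                raise ConfigurationError("non-finite value in simulation config")
        for pair, eff in self.pair_effects.items():
            if not np.isfinite(eff) or eff < 0:
                raise ConfigurationError(f"pair effect for {pair} must be >= 0 and finite")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sampling_rate / 1000.0)) + 1

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, first sample at the epoch start."""
        t0 = self.epoch_window[0]
        return t0 + np.arange(self.n_samples) * 1000.0 / self.sampling_rate


# ---------------------------------------------------------------------------
# Epochs container
# ---------------------------------------------------------------------------


@dataclass
class EpochsSet:
    """Per-subject trial tensor (trials x channels x samples) with labels."""

    subject_id: str
    data: np.ndarray
    labels: np.ndarray  # per-trial category code (str)
    set_tag: np.ndarray  # per-trial "color" / "grayscale"
    layout: SensorLayout
    sampling_rate: float
    t0_offset: float  # ms of the first sample relative to stimulus onset

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.set_tag = np.asarray(self.set_tag, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal the number of trials")
        if len(self.set_tag) != self.data.shape[0]:
            raise ValueError("set_tag length must equal the number of trials")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("channel axis does not match the layout")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def categories(self) -> list[str]:
        """Category codes in order of first appearance."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def sample_index(self, t_ms: float) -> int:
        idx = int(round((t_ms - self.t0_offset) * self.sampling_rate / 1000.0))
        if not (0 <= idx < self.n_samples):
            raise ValueError(f"time {t_ms} ms falls outside the epoch")
        return idx

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Slice of samples covering [start_ms, end_ms], endpoints inclusive."""
        if end_ms < start_ms:
            raise ValueError("window end precedes its start")
        return slice(self.sample_index(start_ms), self.sample_index(end_ms) + 1)

    def baseline_slice(self, start_ms: float, end_ms: float) -> slice:
        """Baseline samples: inclusive of start_ms, exclusive of end_ms."""
        if end_ms <= start_ms:
            raise ValueError("baseline end must exceed its start")
        return slice(self.sample_index(start_ms), self.sample_index(end_ms))

    def copy(self) -> "EpochsSet":
        return EpochsSet(
            subject_id=self.subject_id,
            data=self.data.copy(),
            labels=self.labels.copy(),
            set_tag=self.set_tag.copy(),
            layout=self.layout,
            sampling_rate=self.sampling_rate,
            t0_offset=self.t0_offset,
        )


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _burst(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian-windowed half-sine deflection centered at ``center`` ms."""
    return _gauss(t, center, width) * np.cos(0.5 * np.pi * (t - center) / width)


def _onset_taper(t: np.ndarray, rise_ms: float = 20.0) -> np.ndarray:
    """Smooth 0->1 ramp after stimulus onset; exactly zero in the baseline."""
    return np.clip(t / rise_ms, 0.0, 1.0) ** 2


def _unit_pattern(
    rng: np.random.Generator, times: np.ndarray, n_channels: int
) -> np.ndarray:
    """Random unit-Frobenius-norm spatiotemporal pattern supported post-onset."""
    spatial = rng.standard_normal(n_channels)
    center = rng.uniform(120.0, 320.0)
    width = rng.uniform(25.0, 60.0)
    temporal = _gauss(times, center, width) * _onset_taper(times)
    pat = np.outer(spatial, temporal)
    nrm = np.linalg.norm(pat)
    if nrm == 0:
        raise RuntimeError("degenerate pattern draw")
    return pat / nrm


def _standardized_trait(
    cfg: SimulationConfig, traits: TraitProfile | None, name: str, pair: tuple[str, str]
) -> float:
    if traits is None:
        raise ConfigurationError(
            f"pair {pair} has trait coupling but no trait profile was given"
        )
    score = traits.score(name)
    if score is None:
        raise ConfigurationError(
            f"trait {name!r} required for pair {pair} is missing for {traits.subject_id}"
        )
    lo, hi = dict(cfg.trait_bounds).get(name, IRI_RANGE)
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)
    return (score - mid) / sd


def category_templates(
    cfg: SimulationConfig,
    design: StimulusDesign,
    layout: SensorLayout,
    traits: TraitProfile | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free per-category templates (channels x samples).

    All categories share a common evoked waveform (main peak at
    ``cfg.peak_latency_ms`` over posterior sensors plus a secondary ~170 ms
    deflection); emotional categories add a sustained 200-350 ms component.
    Each category receives a unique unit-norm pattern of amplitude
    ``category_amplitude``, and each configured pair an extra pattern, added
    to the pair's second category, of amplitude
    ``base_effect * max(0, 1 + beta * z_trait)``.  Templates have exactly zero
    mean over the baseline window.
    """
    cfg.validate()
    times = cfg.times
    C = layout.n_channels
    taper = _onset_taper(times)

    # Spatial profile of the shared waveform: strongest over posterior groups.
    idx = np.arange(C, dtype=float)
    post = [
        i
        for i, ch in enumerate(layout.channels)
        if ch.group is not None and "occipital" in ch.group
    ]
    center_idx = float(np.mean(post)) if post else (C - 1) / 2.0
    spatial = 0.2 + _gauss(idx, center_idx, max(C / 6.0, 1.0))

    common = np.outer(
        spatial,
        taper
        * (
            cfg.base_amplitude * _burst(times, cfg.peak_latency_ms, 20.0)
            + 0.6 * cfg.base_amplitude * _burst(times, 170.0, 30.0)
        ),
    )
    sustained = np.outer(
        0.8 * spatial, taper * 0.5 * cfg.base_amplitude * _burst(times, 275.0, 60.0)
    )

    templates: dict[str, np.ndarray] = {}
    for k, cat in enumerate(design.categories):
        tmpl = common.copy()
        if cat in cfg.emotional_categories:
            tmpl += sustained
        if cfg.category_amplitude != 0.0:
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.pattern_seed & 0x7FFFFFFF, 1, k])
            )
            tmpl += cfg.category_amplitude * _unit_pattern(rng, times, C)
        templates[cat] = tmpl

    for j, (pair, base) in enumerate(sorted(cfg.pair_effects.items())):
        a, b = pair
        if a not in templates or b not in templates:
            raise ConfigurationError(f"pair {pair} references unknown categories")
        amp = float(base)
        coupling = dict(cfg.trait_coupling).get(pair)
        if coupling is not None:
            name, beta = coupling
            if beta != 0.0:
                z = _standardized_trait(cfg, traits, name, pair)
                amp = base * max(0.0, 1.0 + beta * z)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.pattern_seed & 0x7FFFFFFF, 2, j])
        )
        templates[b] = templates[b] + amp * _unit_pattern(rng, times, C)

    # Enforce exact zero mean over the baseline (pre-onset) samples.
    n_base = int(round(-cfg.epoch_window[0] * cfg.sampling_rate / 1000.0))
    for cat, tmpl in templates.items():
        tmpl -= tmpl[:, :n_base].mean(axis=1, keepdims=True)
    return templates


def pair_separation(
    cfg: SimulationConfig,
    design: StimulusDesign,
    layout: SensorLayout,
    pair: tuple[str, str],
    traits: TraitProfile | None = None,
) -> float:
    """L2 norm of the template difference for a category pair."""
    t = category_templates(cfg, design, layout, traits)
    return float(np.linalg.norm(t[pair[0]] - t[pair[1]]))


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, phi: float
) -> np.ndarray:
    """Stationary Gaussian AR(1) noise along the last axis, marginal SD ``sd``."""
    e = rng.standard_normal(shape)
    e[..., 0] *= sd
    if shape[-1] > 1:
        e[..., 1:] *= sd * math.sqrt(1.0 - phi * phi)
    if phi == 0.0:
        return e
    return lfilter([1.0], [1.0, -phi], e, axis=-1)


def _mix_channels(x: np.ndarray, width: int) -> np.ndarray:
    """Variance-preserving Gaussian mixing across the channel axis (axis 1).

    The kernel is renormalized to unit L2 norm at every position (including
    edges), so the per-channel marginal SD is unchanged for independent
    input channels.
    """
    if width <= 1 or x.shape[1] <= 1:
        return x
    half = max(1, width // 2)
    offs = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offs / (width / 3.0)) ** 2)
    C = x.shape[1]
    padded = np.pad(x, ((0, 0), (half, half), (0, 0)))
    ones = np.pad(np.ones(C), (half, half))
    acc = np.zeros_like(x)
    norm = np.zeros(C)
    for k, wk in zip(offs, w):
        acc += wk * padded[:, half + k : half + k + C, :]
        norm += wk * wk * ones[half + k : half + k + C]
    return acc / np.sqrt(norm)[None, :, None]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_subject(
    cfg: SimulationConfig,
    design: StimulusDesign,
    layout: SensorLayout,
    traits: TraitProfile | None = None,
    seed: int = 0,
    subject_id: str | None = None,
) -> EpochsSet:
    """Simulate one subject's epochs: ``category template + AR(1) noise``.

    Identical inputs and seed give a bitwise-identical trial tensor.  Color
    and grayscale sets are generated from the same template (the set tag is a
    label only), matching an analysis that pools both sets.
    """
    cfg.validate()
    design = make_design(design)
    if traits is not None:
        traits.validate(cfg.trait_bounds or None)
    needs_traits = any(beta != 0.0 for (_, beta) in dict(cfg.trait_coupling).values())
    if needs_traits and traits is None:
        raise ConfigurationError("trait coupling is configured but no traits were given")

    templates = category_templates(cfg, design, layout, traits)
    per_set = design.trials_per_category_per_set
    labels: list[str] = []
    tags: list[str] = []
    for set_name in design.sets:
        for cat in design.categories:
            labels.extend([cat] * per_set)
            tags.extend([set_name] * per_set)
    n_trials = len(labels)
    C, S = layout.n_channels, cfg.n_samples

    data = np.empty((n_trials, C, S), dtype=np.float64)
    for i, lab in enumerate(labels):
        data[i] = templates[lab]

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = _ar1_noise(rng, (n_trials, C, S), cfg.noise_sd, cfg.ar1_coef)
        # Mix within each modality block separately.
        gi, ei = layout.grad_indices, layout.eeg_indices
        if len(gi):
            noise[:, gi, :] = _mix_channels(noise[:, gi, :], cfg.spatial_mixing_width)
        if len(ei):
            noise[:, ei, :] = _mix_channels(noise[:, ei, :], cfg.spatial_mixing_width)
        data += noise

    sid = subject_id or (traits.subject_id if traits is not None else "S01")
    return EpochsSet(
        subject_id=sid,
        data=data,
        labels=np.array(labels, dtype=object),
        set_tag=np.array(tags, dtype=object),
        layout=layout,
        sampling_rate=cfg.sampling_rate,
        t0_offset=cfg.epoch_window[0],
    )


def simulate_cohort(
    cfg: SimulationConfig,
    design: StimulusDesign,
    layout: SensorLayout,
    trait_sampler: Callable[[np.random.Generator, str], TraitProfile] | None = None,
    seed: int = 0,
) -> list[tuple[EpochsSet, TraitProfile]]:
    """Simulate ``cfg.n_subjects`` subjects with per-subject derived seeds.

    Traits are drawn from ``trait_sampler`` (default: independent uniform per
    subscale over the IRI range) and returned alongside each epochs set.
    """
    cfg.validate()
    sampler = trait_sampler or uniform_trait_sampler()
    out: list[tuple[EpochsSet, TraitProfile]] = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        trng = np.random.default_rng(derive_seed(seed, "traits", i))
        traits = sampler(trng, sid)
        ep = simulate_subject(
            cfg, design, layout, traits, seed=derive_seed(seed, "epochs", i), subject_id=sid
        )
        out.append((ep, traits))
    return out
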