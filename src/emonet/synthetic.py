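"""Synthetic lead fields, EEG sessions, and rating tables.

Every downstream stage of the pipeline is testable without access to the
study's (unreleased) recordings because this module generates:

* random lead fields with a source -> region partition over the 68
  Desikan-Killiany cortical regions,
* multichannel EEG sessions in which selected region pairs share a
  band-limited source component with a configurable mixing weight ρ, only
  in a designated (emotion class, scenario) condition — so the planted
  ground truth is recoverable by construction, and
* rating tables drawn from truncated normals at configurable per-condition
  means/SDs on the printed scales (SAM 1-9, vocal self-rating 1-4,
  third-party 1-10), defaulting to the study's reported condition means.

Source signals are sums of five unit-variance band-limited Gaussian
components; the coupling x_j <- sqrt(1-ρ²)·x_j + ρ·x_i on the planted band
component makes the expected within-band Pearson correlation of the pair
analytically ≈ ρ. Sensor data are gain·sources plus white noise scaled to
RMS(signal)/RMS(noise) = ``noise_snr``. No head geometry, forward BEM
solve, or ocular/muscle artifacts are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .connectivity import DEFAULT_BANDS
from .errors import InvalidSpecError
from .preprocess import EpochLabel, Recording, design_bandpass_fir, _filter_zero_phase
from .scale_stats import (EMOTIONS, SAM_ITEMS, SCALE_BOUNDS, SCENARIOS,
                          VOCAL_ITEMS)

#: Desikan-Killiany gyral labels, 34 per hemisphere.
_DK_BASE = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)
DK_REGION_NAMES: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _DK_BASE
)

#: Head-tissue conductivities reported for the study's three-shell model
#: (scalp, skull, brain, in S/m). Inert metadata: no forward solve happens here.
DEFAULT_CONDUCTIVITIES = {"scalp": 1.0, "skull": 0.0125, "brain": 1.0}


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------

@dataclass
class LeadField:
    """Sensors x sources gain matrix with a source -> region partition."""

    gain: np.ndarray
    region_of_source: np.ndarray
    region_names: list[str]
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=np.float64)
        self.region_of_source = np.asarray(self.region_of_source, dtype=np.intp)
        n_regions = len(self.region_names)
        if self.gain.ndim != 2:
            raise InvalidSpecError("gain must be 2-D (sensors x sources)")
        if self.region_of_source.shape[0] != self.gain.shape[1]:
            raise InvalidSpecError("one region index required per source")
        counts = np.bincount(self.region_of_source, minlength=n_regions)
        if self.region_of_source.min(initial=0) < 0 or \
                self.region_of_source.max(initial=0) >= n_regions:
            raise InvalidSpecError("region indices out of range")
        if (counts == 0).any():
            raise InvalidSpecError(
                f"regions without sources: {np.flatnonzero(counts == 0).tolist()}"
            )

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def make_lead_field(n_sensors: int, n_sources: int, n_regions: int = 68,
                    seed: int = 0, identity: bool = False) -> LeadField:
    """Random (or identity) synthetic lead field with a covering partition.

    The first ``n_regions`` sources are assigned one per region so every
    region is non-empty; the remainder are spread round-robin. Gaussian
    gains are generically full column-rank for ``n_sensors >= n_sources``.
    """
    if n_regions < 1 or n_sensors < 2:
        raise InvalidSpecError("need n_regions >= 1 and n_sensors >= 2")
    if n_regions > n_sources:
        raise InvalidSpecError(
            f"n_regions={n_regions} > n_sources={n_sources}: every region "
            "needs at least one source"
        )
    region_of_source = np.arange(n_sources) % n_regions
    if n_regions == 68:
        names = list(DK_REGION_NAMES)
    else:
        names = [f"region{r:02d}" for r in range(n_regions)]
    if identity:
        if n_sensors != n_sources:
            raise InvalidSpecError("identity gain requires n_sensors == n_sources")
        gain = np.eye(n_sensors)
    else:
        rng = np.random.default_rng(seed)
        gain = rng.standard_normal((n_sensors, n_sources))
        norms = np.linalg.norm(gain, axis=0)
        if (norms == 0).any():  # pragma: no cover - probability zero
            raise InvalidSpecError("zero gain column generated")
        gain /= norms
    return LeadField(gain, region_of_source, names,
                     {"conductivities_S_per_m": dict(DEFAULT_CONDUCTIVITIES),
                      "seed": seed})


def save_lead_field(lf: LeadField, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("region_of_source", data=lf.region_of_source)
        f.create_dataset("region_names",
                         data=np.array(lf.region_names, dtype="S64"))
        cond = lf.metadata.get("conductivities_S_per_m")
        if cond:
            for k, v in cond.items():
                f.attrs[f"conductivity_{k}_S_per_m"] = v


def load_lead_field(path) -> LeadField:
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["region_names"][()]]
        cond = {k.removeprefix("conductivity_").removesuffix("_S_per_m"): float(v)
                for k, v in f.attrs.items() if k.startswith("conductivity_")}
        return LeadField(f["gain"][()], f["region_of_source"][()], names,
                         {"conductivities_S_per_m": cond} if cond else {})


# ---------------------------------------------------------------------------
# EEG session simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    """One planted coupling: unordered region pair, band, mixing weight."""

    region_i: int
    region_j: int
    band: str
    rho: float


@dataclass
class SimSpec:
    """Study-design parameters for a simulated session.

    Defaults mirror the study conditions: 16 subjects, two scenarios, three
    emotion classes with two 3-minute songs each, 1,000 Hz sampling, and a
    linear sensor SNR of 3.
    """

    n_subjects: int = 16
    scenarios: tuple[str, ...] = SCENARIOS
    classes: tuple[str, ...] = EMOTIONS
    songs_per_class: int = 2
    duration_s: float = 180.0
    rate: float = 1000.0
    planted_pairs: Mapping[tuple[str, str], Sequence[PlantedPair]] = \
        dc_field(default_factory=dict)
    noise_snr: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.songs_per_class < 1:
            raise InvalidSpecError("need at least one subject and one song per class")
        if self.duration_s <= 0 or self.rate <= 0:
            raise InvalidSpecError("duration and rate must be positive")
        if self.noise_snr <= 0:
            raise InvalidSpecError("noise_snr must be positive")
        for (cls, scen), pairs in self.planted_pairs.items():
            if cls not in self.classes or scen not in self.scenarios:
                raise InvalidSpecError(
                    f"planted condition ({cls!r}, {scen!r}) not in the design"
                )
            for p in pairs:
                if p.band not in DEFAULT_BANDS:
                    raise InvalidSpecError(
                        f"planted band {p.band!r} not one of {list(DEFAULT_BANDS)}"
                    )
                if not 0.0 <= p.rho <= 1.0:
                    raise InvalidSpecError(f"rho={p.rho} outside [0, 1]")
                if p.region_i == p.region_j:
                    raise InvalidSpecError("planted pair must have i != j")


@dataclass
class SimulatedSong:
    """One simulated recording with its design labels."""

    recording: Recording
    label: EpochLabel


def _band_kernels(rate: float, n_t: int) -> dict[str, np.ndarray]:
    return {b: design_bandpass_fir(lo, hi, rate, max_taps=3 * n_t)
            for b, (lo, hi) in DEFAULT_BANDS.items()}


def _unit_band_noise(rng: np.random.Generator, kernel: np.ndarray,
                     shape: tuple[int, ...]) -> np.ndarray:
    x = _filter_zero_phase(rng.standard_normal(shape), kernel)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_song_sources(lead_field: LeadField, spec: SimSpec, cls: str,
                          scenario: str, rng: np.random.Generator
                          ) -> np.ndarray:
    """Region-level source signals (n_regions x n_t) for one song.

    All sources of a region carry the region's signal, so the planted
    coupling survives parcellation exactly.
    """
    n_t = int(round(spec.duration_s * spec.rate))
    n_regions = lead_field.n_regions
    kernels = _band_kernels(spec.rate, n_t)
    comps = {b: _unit_band_noise(rng, k, (n_regions, n_t))
             for b, k in kernels.items()}
    for p in spec.planted_pairs.get((cls, scenario), ()):
        c = comps[p.band]
        c[p.region_j] = np.sqrt(1.0 - p.rho ** 2) * c[p.region_j] \
            + p.rho * c[p.region_i]
    n_bands = len(comps)
    return sum(comps.values()) / np.sqrt(n_bands)


def simulate_session(lead_field: LeadField, spec: SimSpec
                     ) -> tuple[list[SimulatedSong], dict]:
    """Simulate every (subject, scenario, song) recording of the design.

    Returns the recordings with labels plus a ground-truth record of the
    planted pairs and the per-song label bookkeeping. Deterministic under
    ``spec.seed``.
    """
    songs: list[SimulatedSong] = []
    song_index = {}
    root = np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 7])
    n_runs = (spec.n_subjects * len(spec.scenarios) * len(spec.classes)
              * spec.songs_per_class)
    children = iter(root.spawn(n_runs))
    for subject in range(spec.n_subjects):
        for scenario in spec.scenarios:
            song_no = 0
            for cls in spec.classes:
                for _ in range(spec.songs_per_class):
                    rng = np.random.default_rng(next(children))
                    sources = simulate_song_sources(lead_field, spec, cls,
                                                    scenario, rng)
                    sensor = lead_field.gain[:, :] @ \
                        sources[lead_field.region_of_source]
                    rms = np.sqrt(np.mean(sensor ** 2))
                    noise_sd = rms / spec.noise_snr
                    sensor = sensor + noise_sd * rng.standard_normal(sensor.shape)
                    label = EpochLabel(subject, scenario, cls, song_no)
                    rec = Recording(sensor, spec.rate,
                                    meta={"subject": subject,
                                          "scenario": scenario,
                                          "emotion": cls, "song": song_no})
                    songs.append(SimulatedSong(rec, label))
                    song_index[(subject, scenario, song_no)] = cls
                    song_no += 1
    ground_truth = {
        "planted_pairs": {
            f"{cls}|{scen}": [
                {"region_i": p.region_i, "region_j": p.region_j,
                 "band": p.band, "rho": p.rho} for p in pairs]
            for (cls, scen), pairs in spec.planted_pairs.items()},
        "song_labels": {f"{s}|{scen}|{song}": cls
                        for (s, scen, song), cls in song_index.items()},
        "seed": spec.seed,
    }
    return songs, ground_truth


# ---------------------------------------------------------------------------
# Rating tables
# ---------------------------------------------------------------------------

@dataclass
class RatingSpec:
    """Truncated-normal score model per (scale, item, emotion, scenario).

    ``means`` maps (scale, item, emotion, scenario) to a mean on the
    scale's range; ``sds`` likewise (a scalar applies everywhere). Scores
    are drawn from the normal truncated to the scale bounds, rounded to the
    integer grid of the printed forms, and clipped.
    """

    means: Mapping[tuple[str, str, str, str], float]
    sds: Mapping[tuple[str, str, str, str], float] | float = 1.0
    n_subjects: int = 16
    seed: int = 0

    def sd_for(self, key) -> float:
        if isinstance(self.sds, (int, float)):
            return float(self.sds)
        return float(self.sds[key])

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidSpecError("need at least 2 subjects")
        for key, mean in self.means.items():
            scale = key[0]
            if scale not in SCALE_BOUNDS:
                raise InvalidSpecError(f"unknown scale {scale!r}")
            lo, hi = SCALE_BOUNDS[scale]
            if not lo <= mean <= hi:
                raise InvalidSpecError(
                    f"mean {mean} outside bounds [{lo}, {hi}] for {key}"
                )
            if self.sd_for(key) < 0:
                raise InvalidSpecError(f"negative SD for {key}")


def simulate_ratings(spec: RatingSpec) -> pd.DataFrame:
    """Draw a tidy rating table from the spec; deterministic under seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 11]))
    rows = []
    for key in sorted(spec.means):
        scale, item, emotion, scenario = key
        lo, hi = SCALE_BOUNDS[scale]
        mean, sd = spec.means[key], spec.sd_for(key)
        if sd == 0:
            scores = np.full(spec.n_subjects, float(np.clip(round(mean), lo, hi)))
        else:
            # truncated normal on the scale range, then integer rounding
            u = rng.uniform(size=spec.n_subjects)
            a, b = (lo - mean) / sd, (hi - mean) / sd
            scores = truncnorm.ppf(u, a, b, loc=mean, scale=sd)
            scores = np.clip(np.round(scores), lo, hi)
        for subj, score in enumerate(scores):
            rows.append((subj, scenario, emotion, scale, item, float(score)))
    return pd.DataFrame(rows, columns=["subject", "scenario", "emotion",
                                       "scale", "item", "score"])


#: Condition means reported for the three rating scales, keyed by
#: (scale, item, emotion, scenario). These are the generator's defaults so a
#: synthetic study reproduces the reported mean structure.
REPORTED_RATING_MEANS: dict[tuple[str, str, str, str], float] = {}


def _fill_reported_means():
    sam = {  # (emotion, item): (self, vr)
        ("negative", "pleasure"): (4.69, 3.00),
        ("negative", "activation"): (5.56, 7.00),
        ("negative", "dominance"): (6.06, 4.63),
        ("neutral", "pleasure"): (5.94, 6.19),
        ("neutral", "activation"): (5.69, 6.13),
        ("neutral", "dominance"): (6.50, 6.69),
        ("positive", "pleasure"): (7.00, 8.06),
        ("positive", "activation"): (6.31, 7.56),
        ("positive", "dominance"): (6.44, 6.06),
    }
    vocal = {
        ("negative", "coherence"): (2.81, 3.25),
        ("negative", "breath"): (2.69, 3.06),
        ("negative", "resonance"): (2.50, 3.06),
        ("negative", "intonation"): (2.94, 3.06),
        ("negative", "language"): (2.94, 3.06),
        ("negative", "musicality"): (3.16, 3.44),
        ("negative", "expression"): (2.75, 3.31),
        ("neutral", "coherence"): (3.25, 3.38),
        ("neutral", "breath"): (3.19, 3.38),
        ("neutral", "resonance"): (2.88, 3.25),
        ("neutral", "intonation"): (3.13, 3.31),
        ("neutral", "language"): (3.06, 3.38),
        ("neutral", "musicality"): (3.44, 3.56),
        ("neutral", "expression"): (3.00, 3.44),
        ("positive", "coherence"): (3.31, 3.44),
        ("positive", "breath"): (3.13, 3.31),
        ("positive", "resonance"): (3.19, 3.06),
        ("positive", "intonation"): (2.69, 3.00),
        ("positive", "language"): (3.00, 3.31),
        ("positive", "musicality"): (3.38, 3.31),
        ("positive", "expression"): (3.25, 3.63),
    }
    third = {
        ("negative", "coherence"): (6.66, 6.95),
        ("negative", "breath"): (6.39, 6.98),
        ("negative", "resonance"): (6.34, 6.96),
        ("negative", "intonation"): (6.18, 6.26),
        ("negative", "language"): (6.66, 6.58),
        ("negative", "musicality"): (6.58, 7.34),
        ("negative", "expression"): (6.61, 7.81),
        ("neutral", "coherence"): (6.73, 7.00),
        ("neutral", "breath"): (6.65, 7.13),
        ("neutral", "resonance"): (6.58, 7.38),
        ("neutral", "intonation"): (6.29, 6.36),
        ("neutral", "language"): (6.64, 6.63),
        ("neutral", "musicality"): (6.89, 7.35),
        ("neutral", "expression"): (6.98, 7.73),
        ("positive", "coherence"): (6.80, 7.10),
        ("positive", "breath"): (6.60, 7.08),
        ("positive", "resonance"): (6.56, 7.39),
        ("positive", "intonation"): (6.38, 6.45),
        ("positive", "language"): (6.69, 6.68),
        ("positive", "musicality"): (6.70, 7.41),
        ("positive", "expression"): (6.71, 7.75),
    }
    for table, scale in ((sam, "SAM"), (vocal, "self_vocal"),
                         (third, "third_party")):
        for (emotion, item), (m_self, m_vr) in table.items():
            REPORTED_RATING_MEANS[(scale, item, emotion, "self")] = m_self
            REPORTED_RATING_MEANS[(scale, item, emotion, "vr")] = m_vr


_fill_reported_means()

#: Per-scale score SDs for the default generator (not reported by the study;
#: chosen as plausible spreads relative to each scale's range).
DEFAULT_RATING_SDS = {"SAM": 1.5, "self_vocal": 0.5, "third_party": 0.7}


def default_rating_spec(n_subjects: int = 16, seed: int = 0,
                        null: bool = False) -> RatingSpec:
    """The study-shaped rating spec: reported means (or a zero-effect null
    where both scenarios share the self-scenario mean), default SDs."""
    means = dict(REPORTED_RATING_MEANS)
    if null:
        for (scale, item, emo, scen) in list(means):
            means[(scale, item, emo, scen)] = \
                REPORTED_RATING_MEANS[(scale, item, emo, "self")]
    sds = {key: DEFAULT_RATING_SDS[key[0]] for key in means}
    return RatingSpec(means, sds, n_subjects, seed)


# ---------------------------------------------------------------------------
# EDF export
# ---------------------------------------------------------------------------

def write_edf(path, rec: Recording, physical_range: tuple[float, float] | None = None
              ) -> None:
    """Write a recording as EDF+ (16-bit), 1-second data records.

    The sampling rate must be a positive integer; a trailing partial second
    is zero-padded to complete the final data record.
    """
    rate = int(round(rec.rate))
    if rate <= 0 or abs(rate - rec.rate) > 1e-9:
        raise InvalidSpecError("EDF export requires an integer sampling rate")
    n_ch, n_samp = rec.data.shape
    n_records = int(np.ceil(n_samp / rate))
    data = np.zeros((n_ch, n_records * rate))
    data[:, :n_samp] = rec.data
    if physical_range is None:
        lim = max(1e-6, float(np.max(np.abs(data))))
        pmin, pmax = -lim, lim
    else:
        pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scaled = (data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    digital = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    names = list(rec.channel_names or [f"EEG{i:03d}" for i in range(n_ch)])

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii", "replace")[:n].ljust(n)

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("EDF+C", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(f"EEG {n}", 16) for n in names),
        b"".join(pad("AgAgCl electrode", 80) for _ in names),
        b"".join(pad("uV", 8) for _ in names),
        b"".join(pad(f"{pmin:.6g}", 8) for _ in names),
        b"".join(pad(f"{pmax:.6g}", 8) for _ in names),
        b"".join(pad(str(dmin), 8) for _ in names),
        b"".join(pad(str(dmax), 8) for _ in names),
        b"".join(pad("", 80) for _ in names),
        b"".join(pad(str(rate), 8) for _ in names),
        b"".join(pad("", 32) for _ in names),
    ])
    with open(path, "wb") as f:
        f.write(header + sig)
        for r in range(n_records):
            f.write(digital[:, r * rate:(r + 1) * rate].tobytes())


def read_recording(path, *, preload: bool = True) -> Recording:
    """Read an EDF or BrainVision file into a :class:`Recording` (via mne)."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=preload, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=preload, verbose="error")
    else:
        raise InvalidSpecError(f"unsupported recording format: {path.suffix}")
    data = raw.get_data() * 1e6  # mne returns volts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return Recording(data, float(raw.info["sfreq"]), names)
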