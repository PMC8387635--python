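"""Band-limited Pearson functional connectivity and feature vectorization.

Region time courses are decomposed into the five canonical EEG rhythms
(delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz), a Pearson
correlation matrix is computed per 1-s epoch and band, and the strict upper
triangles are concatenated delta->gamma into one feature vector: with 68
regions that is 68*67/2 = 2,278 features per band and 11,390 in total.

Per-epoch band filtering uses reflect padding of one epoch length to tame
edge transients; note that a 1-s window holds fewer than four delta cycles,
so delta-band correlations are intrinsically noisy at this window length —
a property of the epoching convention itself, reproduced as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, InvalidBandError, SchemaError, ShapeError
from .preprocess import design_bandpass_fir, _filter_zero_phase
from .source_model import RegionEpochs

logger = logging.getLogger(__name__)

#: Canonical band edges in Hz, in the fixed concatenation order.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

BAND_ORDER: tuple[str, ...] = tuple(DEFAULT_BANDS)


def validate_bands(bands: dict[str, tuple[float, float]], rate: float) -> None:
    edges = sorted(bands.values())
    for low, high in edges:
        if not (0 < low < high < rate / 2):
            raise InvalidBandError(
                f"band ({low}, {high}) Hz invalid at rate {rate} Hz"
            )
    for (_, hi), (lo, _) in zip(edges, edges[1:]):
        if lo < hi:
            raise InvalidBandError("bands must have non-overlapping interiors")


def band_decompose(region_epochs: RegionEpochs,
                   bands: dict[str, tuple[float, float]] | None = None,
                   ) -> dict[str, RegionEpochs]:
    """Zero-phase band-pass each epoch into every band; shapes preserved."""
    bands = DEFAULT_BANDS if bands is None else bands
    validate_bands(bands, region_epochs.rate)
    n_t = region_epochs.data.shape[-1]
    out: dict[str, RegionEpochs] = {}
    for name, (low, high) in bands.items():
        kernel = design_bandpass_fir(low, high, region_epochs.rate,
                                     max_taps=3 * n_t)
        filtered = _filter_zero_phase(region_epochs.data, kernel)
        out[name] = RegionEpochs(filtered, region_epochs.rate,
                                 region_epochs.labels,
                                 region_epochs.region_names)
    return out


def fc_matrix(epoch: np.ndarray) -> np.ndarray:
    """Pearson correlation between all region pairs of one epoch.

    ``epoch`` is regions x samples. Zero-variance regions get zeroed rows
    and columns (with a logged warning) instead of NaN; the diagonal is 1.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ShapeError("fc_matrix expects a 2-D (regions x samples) array")
    if epoch.shape[1] < 3:
        raise ShapeError(f"need >= 3 samples per epoch, got {epoch.shape[1]}")
    centered = epoch - epoch.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered ** 2).mean(axis=1))
    flat = sd == 0
    if flat.any():
        logger.warning("zero-variance regions %s: FC rows/columns set to 0",
                       np.flatnonzero(flat).tolist())
    safe_sd = np.where(flat, 1.0, sd)
    z = centered / safe_sd[:, None]
    r = (z @ z.T) / epoch.shape[1]
    r = np.clip(r, -1.0, 1.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def fc_matrices(band_epochs: dict[str, RegionEpochs]
                ) -> dict[str, np.ndarray]:
    """Per-band stacks of per-epoch FC matrices (epochs x R x R)."""
    return {
        band: np.stack([fc_matrix(ep) for ep in re.data])
        for band, re in band_epochs.items()
    }


def _feature_names(n_regions: int, bands: tuple[str, ...] = BAND_ORDER,
                   region_names: list[str] | None = None) -> list[str]:
    iu, ju = np.triu_indices(n_regions, k=1)
    names = []
    for band in bands:
        for i, j in zip(iu, ju):
            a = region_names[i] if region_names else str(i)
            b = region_names[j] if region_names else str(j)
            names.append(f"{band}:{a}|{b}")
    return names


def vectorize_fc(fc_by_band: dict[str, np.ndarray],
                 region_names: list[str] | None = None,
                 bands: tuple[str, ...] = BAND_ORDER,
                 ) -> tuple[np.ndarray, list[str]]:
    """Concatenate strict upper triangles, band order fixed delta->gamma."""
    missing = [b for b in bands if b not in fc_by_band]
    if missing:
        raise SchemaError(f"missing band matrices: {missing}")
    first = next(iter(fc_by_band.values()))
    n_regions = first.shape[0]
    iu, ju = np.triu_indices(n_regions, k=1)
    parts = []
    for band in bands:
        m = np.asarray(fc_by_band[band], dtype=np.float64)
        if m.shape != (n_regions, n_regions):
            raise ShapeError(f"band {band} matrix has shape {m.shape}")
        if np.max(np.abs(m - m.T)) > 1e-9:
            raise IntegrityError(f"band {band} FC matrix is not symmetric")
        parts.append(m[iu, ju])
    return np.concatenate(parts), _feature_names(n_regions, bands, region_names)


def devectorize_fc(vector: np.ndarray, n_regions: int,
                   bands: tuple[str, ...] = BAND_ORDER,
                   ) -> dict[str, np.ndarray]:
    """Inverse of :func:`vectorize_fc` with unit diagonal."""
    n_pairs = n_regions * (n_regions - 1) // 2
    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != n_pairs * len(bands):
        raise ShapeError(
            f"vector length {vector.size} != {len(bands)} bands x {n_pairs} pairs"
        )
    iu, ju = np.triu_indices(n_regions, k=1)
    out = {}
    for k, band in enumerate(bands):
        m = np.eye(n_regions)
        m[iu, ju] = vector[k * n_pairs:(k + 1) * n_pairs]
        m[ju, iu] = m[iu, ju]
        out[band] = m
    return out


@dataclass
class FeatureTable:
    """Samples x connectivity-features matrix with labels and grouping keys."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    groups: pd.DataFrame  # columns: subject, scenario, song
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ShapeError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ShapeError(
                f"{len(self.feature_names)} names for {self.X.shape[1]} features"
            )
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.groups):
            raise ShapeError("X, y and groups must have equal sample counts")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def band_columns(self, band: str) -> np.ndarray:
        idx = np.array([i for i, n in enumerate(self.feature_names)
                        if n.split(":", 1)[0] == band])
        if idx.size == 0:
            raise SchemaError(f"no features tagged with band '{band}'")
        return idx

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[mask], self.feature_names, self.y[mask],
                            self.groups.iloc[mask].reset_index(drop=True),
                            dict(self.meta))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "emotion", self.y)
        for k, col in enumerate(["subject", "scenario", "song"]):
            df.insert(k, col, self.groups[col].to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        label_cols = ["subject", "scenario", "song", "emotion"]
        feats = [c for c in df.columns if c not in label_cols]
        return cls(df[feats].to_numpy(float), feats,
                   df["emotion"].to_numpy(),
                   df[["subject", "scenario", "song"]].copy())


def build_feature_table(band_epochs: dict[str, RegionEpochs],
                        bands: tuple[str, ...] = BAND_ORDER) -> FeatureTable:
    """FC features for every epoch: one row per epoch, 5·R(R−1)/2 columns."""
    missing = [b for b in bands if b not in band_epochs]
    if missing:
        raise SchemaError(f"missing band blocks: {missing}")
    ref = band_epochs[bands[0]]
    n_regions = ref.data.shape[1]
    iu, ju = np.triu_indices(n_regions, k=1)
    blocks = []
    for band in bands:
        re = band_epochs[band]
        rows = np.empty((re.n_epochs, iu.size))
        for e in range(re.n_epochs):
            rows[e] = fc_matrix(re.data[e])[iu, ju]
        blocks.append(rows)
    X = np.concatenate(blocks, axis=1)
    names = _feature_names(n_regions, bands, ref.region_names)
    groups = pd.DataFrame(
        {"subject": [lab.subject for lab in ref.labels],
         "scenario": [lab.scenario for lab in ref.labels],
         "song": [lab.song for lab in ref.labels]}
    )
    return FeatureTable(X, names, ref.y, groups)
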