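"""Wavelet-based feature extraction per swallow clip.

For each axis the clip is decomposed with the discrete Meyer wavelet to
depth L.  With E_j the energy (sum of squared coefficients) in detail level
j = 1..L and E_{L+1} the approximation-band energy:

    p_j   = E_j / E_tot          relative dyadic-band energies, sum to 1
    E_log = ln(E_tot)            log total wavelet energy
    H     = -sum_j p_j ln p_j    wavelet entropy, 0 <= H <= ln(L+1)

The feature vector concatenates, per axis, the L+1 fractions, the
log-energy and the entropy, then appends the clip duration in seconds:
2*(L+3) + 1 entries.  Duration is included because swallow duration varies
systematically with patient factors (body habitus, head position, age,
sex) and carries screening-relevant information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WAVELET, wavedec
from .segmentation import SwallowClip

AXES = ("ap", "si")


@dataclass(frozen=True)
class FeatureConfig:
    level: int = 10
    wavelet: str = WAVELET

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition depth must be >= 1")

    @property
    def n_features(self) -> int:
        return 2 * (self.level + 3) + 1

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for axis in AXES:
            names += [f"{axis}_relE_d{j}" for j in range(1, self.level + 1)]
            names += [f"{axis}_relE_a{self.level}", f"{axis}_logE", f"{axis}_entropy"]
        names.append("duration_s")
        return names


def _axis_features(x: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    coeffs = wavedec(np.asarray(x, dtype=float), cfg.wavelet, cfg.level)
    # coeffs[0] approximation, coeffs[1] coarsest detail ... coeffs[-1] finest
    energies = np.array([np.sum(c**2) for c in coeffs])
    e_tot = energies.sum()
    if e_tot <= 0:
        raise ValueError("zero-energy clip: features undefined")
    # order fractions finest detail (d1) ... coarsest (dL), then approximation
    p_details = energies[1:][::-1] / e_tot
    p_approx = energies[0] / e_tot
    p = np.concatenate([p_details, [p_approx]])
    with np.errstate(divide="ignore", invalid="ignore"):
        h = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    return np.concatenate([p, [np.log(e_tot), h]])


def extract_features(clip: SwallowClip, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Deterministic fixed-length descriptor of one clip (both axes)."""
    if clip.n_samples < 2 ** cfg.level:
        raise ValueError(
            f"clip {clip.key} of {clip.n_samples} samples too short for depth {cfg.level}"
        )
    vec = np.concatenate(
        [_axis_features(clip.ap, cfg), _axis_features(clip.si, cfg), [clip.duration_s]]
    )
    assert len(vec) == cfg.n_features
    return vec


KEY_COLUMNS = ["participant_id", "task_id", "bolus_id", "subswallow_index"]


def build_feature_table(
    clips: list[SwallowClip], cfg: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """One row per clip: key columns then feature columns, in a fixed order."""
    keys = [c.key for c in clips]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate clip keys in feature table")
    names = cfg.feature_names()
    rows = []
    for clip in clips:
        row = dict(zip(KEY_COLUMNS, clip.key))
        row.update(zip(names, extract_features(clip, cfg)))
        rows.append(row)
    return pd.DataFrame(rows, columns=KEY_COLUMNS + names)
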