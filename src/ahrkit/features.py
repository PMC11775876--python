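"""Per-epoch summary features for the static/dynamic gate and posture model.

36 features per 6-s epoch, in a fixed documented order: ten per axis (mean,
maximum, minimum, range, variance, standard deviation, skewness, kurtosis,
inclination, zero-crossing rate), three for the gravity-corrected VM (mean,
variance, standard deviation) and the three pairwise axis correlations.

Conventions for quantities the underlying method leaves open: moments are
population moments with kurtosis reported as excess kurtosis; zero-variance
(constant) axes get skewness, kurtosis and correlation 0; inclination is
the angle (radians) between an axis and the epoch-mean acceleration vector,
arccos(mean_axis / ||(mean_x, mean_y, mean_z)||); zero-crossing rate counts
sign changes of the mean-centred signal per second.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochSet
from .errors import ShapeError

AXES = ("x", "y", "z")
_PER_AXIS = (
    "mean", "max", "min", "range", "var", "std", "skew", "kurt", "incl", "zcr",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ax}_{stat}" for ax in AXES for stat in _PER_AXIS
) + ("vm_mean", "vm_var", "vm_std", "r_xy", "r_xz", "r_yz")


def _zero_crossing_rate(x: np.ndarray, fs: float) -> np.ndarray:
    """Crossings of zero per second after mean-centring; x is (n, samples)."""
    c = x - x.mean(axis=1, keepdims=True)
    crossings = np.sum(c[:, :-1] * c[:, 1:] < 0, axis=1)
    return crossings * fs / x.shape[1]


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise sample Pearson correlation; 0 where either input is constant."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = np.sum(ac * bc, axis=1)
    den = np.sqrt(np.sum(ac**2, axis=1) * np.sum(bc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def extract_features(
    epochs: EpochSet, fs: float = 100.0, expected_samples: int | None = None
) -> pd.DataFrame:
    """36-column feature table, one row per epoch."""
    x = epochs.x
    if expected_samples is not None and x.shape[1] != expected_samples:
        raise ShapeError(
            f"expected {expected_samples} samples per epoch, got {x.shape[1]}"
        )
    cols: dict[str, np.ndarray] = {}
    means = x.mean(axis=1)  # (n, 3)
    norm = np.linalg.norm(means, axis=1)
    for j, ax in enumerate(AXES):
        a = x[:, :, j]
        m = means[:, j]
        var = a.var(axis=1)
        centered = a - m[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            m3 = np.mean(centered**3, axis=1)
            m4 = np.mean(centered**4, axis=1)
            skew = np.where(var > 0, m3 / np.where(var > 0, var, 1.0) ** 1.5, 0.0)
            kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1.0) ** 2 - 3.0, 0.0)
            incl = np.where(norm > 0, np.arccos(np.clip(m / np.where(norm > 0, norm, 1.0), -1, 1)), 0.0)
        cols[f"{ax}_mean"] = m
        cols[f"{ax}_max"] = a.max(axis=1)
        cols[f"{ax}_min"] = a.min(axis=1)
        cols[f"{ax}_range"] = a.max(axis=1) - a.min(axis=1)
        cols[f"{ax}_var"] = var
        cols[f"{ax}_std"] = np.sqrt(var)
        cols[f"{ax}_skew"] = skew
        cols[f"{ax}_kurt"] = kurt
        cols[f"{ax}_incl"] = incl
        cols[f"{ax}_zcr"] = _zero_crossing_rate(a, fs)
    vm = epochs.vm
    cols["vm_mean"] = vm.mean(axis=1)
    cols["vm_var"] = vm.var(axis=1)
    cols["vm_std"] = vm.std(axis=1)
    cols["r_xy"] = _corr(x[:, :, 0], x[:, :, 1])
    cols["r_xz"] = _corr(x[:, :, 0], x[:, :, 2])
    cols["r_yz"] = _corr(x[:, :, 1], x[:, :, 2])
    df = pd.DataFrame(cols)[list(FEATURE_NAMES)]
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("non-finite feature value for a degenerate epoch")
    return df


def standardize_features(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Z-score ``apply_to`` (default: the training set) with training statistics.

    Zero-variance features pass through unscaled, so held-out data cannot
    leak its own distribution into the transform.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    target = train if apply_to is None else apply_to
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    scaler = {"mean": mu.to_dict(), "sd": sd.to_dict()}
    out = _apply(target, mu, sd)
    return out, scaler


def _apply(df: pd.DataFrame, mu: pd.Series, sd: pd.Series) -> pd.DataFrame:
    sd_safe = sd.where(sd > 0, 1.0)
    out = (df - mu) / sd_safe
    frozen = sd.index[sd <= 0]
    out[frozen] = df[frozen]
    return out


def apply_scaler(features: pd.DataFrame, scaler: dict) -> pd.DataFrame:
    return _apply(features, pd.Series(scaler["mean"]), pd.Series(scaler["sd"]))
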