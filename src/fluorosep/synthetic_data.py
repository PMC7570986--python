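"""Seeded generators emulating the study's plate layout and score geometry.

Two generators back the whole test surface without any measured data:

* :func:`generate_spectra` builds replicate emission spectra with the
  study design — 36 samples x 5 replicate wells plus 6 blank wells on a
  301-point 400-700 nm grid — as a smooth blank baseline plus a
  sample-specific mixture of a small number of latent Gaussian emission
  bands, with multiplicative (intensity-proportional) replicate noise.
* :func:`generate_score_groups` places labeled isotropic Gaussian point
  groups directly in score space, with centers on a circle so the
  between-group separation is a single dial.

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .spectra_io import SpectraMatrix


@dataclass
class SyntheticConfig:
    """Design of one synthetic plate (defaults mirror the study layout).

    ``between_sample_spread`` scales the latent band amplitudes relative
    to the blank baseline (1.0 means sample bands comparable in intensity
    to the baseline); ``noise_fraction`` is the relative standard deviation
    of the multiplicative replicate noise (0.01 = 1% photometric
    repeatability, typical of plate-reader fluorescence).
    """

    n_samples: int = 36
    n_replicates: int = 5
    n_blanks: int = 6
    wavelength_lo: float = 400.0
    wavelength_hi: float = 700.0
    n_wavelengths: int = 301
    n_latent: int = 2
    between_sample_spread: float = 1.0
    noise_fraction: float = 0.01
    condition: str = "default"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_replicates", "n_blanks", "n_wavelengths"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.noise_fraction < 0:
            raise ValidationError("noise_fraction must be >= 0")
        if not self.wavelength_lo < self.wavelength_hi:
            raise ValidationError("wavelength_lo must be < wavelength_hi")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_lo, self.wavelength_hi, self.n_wavelengths)

    # key/value round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _gaussian_band(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def generate_spectra(config: SyntheticConfig) -> SpectraMatrix:
    """Synthesize one plate of replicate spectra plus blanks.

    Each sample's mean spectrum is the blank baseline plus a non-negative
    sample-specific mixture of ``n_latent`` smooth Gaussian emission bands
    spread over 430-600 nm; every well (sample replicate or blank) is its
    mean spectrum times (1 + noise) with i.i.d. multiplicative noise.  The
    latent mixing weights give the data an (approximately) ``n_latent``-rank
    structure after centering, so a PCA with that many components leaves
    only noise-driven residual dispersion.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths

    # blank baseline: broad low bands, scale ~100 arbitrary fluorescence units
    baseline = 100.0 * (
        0.6 * _gaussian_band(wl, 450.0, 90.0) + 0.4 * _gaussian_band(wl, 540.0, 120.0)
    ) + 20.0

    centers = np.linspace(440.0, 590.0, config.n_latent) if config.n_latent > 1 \
        else np.array([500.0])
    widths = np.full(config.n_latent, 28.0)
    bands = np.stack([_gaussian_band(wl, c, w) for c, w in zip(centers, widths)])

    # non-negative mixing weights, spread relative to the baseline scale
    amp = 100.0 * config.between_sample_spread
    weights = amp * rng.uniform(0.1, 1.0, size=(config.n_samples, config.n_latent))

    rows, meta_rows = [], []
    well = 0
    for i in range(config.n_samples):
        mean_spec = baseline + weights[i] @ bands
        for r in range(config.n_replicates):
            noise = 1.0 + config.noise_fraction * rng.standard_normal(len(wl))
            rows.append(mean_spec * noise)
            meta_rows.append((f"W{well:03d}", f"S{i + 1:02d}", r + 1, False,
                              config.condition))
            well += 1
    for b in range(config.n_blanks):
        noise = 1.0 + config.noise_fraction * rng.standard_normal(len(wl))
        rows.append(baseline * noise)
        meta_rows.append((f"W{well:03d}", f"blank{b + 1}", b + 1, True,
                          config.condition))
        well += 1

    meta = pd.DataFrame(meta_rows, columns=["well_id", "sample_id", "replicate",
                                            "is_blank", "condition"])
    return SpectraMatrix(np.asarray(rows), wl.copy(), meta)


def generate_conditions(configs: dict[str, SyntheticConfig]) -> SpectraMatrix:
    """Concatenate one plate per condition into a single multi-condition matrix."""
    if not configs:
        raise ValidationError("need at least one condition config")
    parts = []
    for name, cfg in configs.items():
        mat = generate_spectra(cfg)
        meta = mat.well_meta.copy()
        meta["condition"] = name
        meta["well_id"] = name + "_" + meta["well_id"]
        parts.append((mat.values, meta))
        wl = mat.wavelengths
    values = np.vstack([v for v, _ in parts])
    meta = pd.concat([m for _, m in parts], ignore_index=True)
    return SpectraMatrix(values, wl, meta)


def generate_score_groups(
    n_groups: int,
    n_points: int = 5,
    separation: float = 5.0,
    spread: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled isotropic Gaussian groups in the score plane.

    Group centers sit on a circle of radius ``separation`` (one group sits
    at the origin when ``n_groups == 1``); within-group scatter is
    isotropic with standard deviation ``spread``.  Returns ``(points,
    labels)`` with ``n_groups * n_points`` rows.
    """
    if n_points < 3:
        raise ValidationError("need >= 3 points per group")
    if n_groups < 1:
        raise ValidationError("need >= 1 group")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_groups) / max(n_groups, 1)
    centers = separation * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    if n_groups == 1:
        centers = np.zeros((1, 2))
    pts, labels = [], []
    for g in range(n_groups):
        pts.append(centers[g] + spread * rng.standard_normal((n_points, 2)))
        labels += [f"G{g + 1:02d}"] * n_points
    return np.vstack(pts), np.asarray(labels)


def cloud_from_points(points: np.ndarray, labels: np.ndarray,
                      condition: str = "synthetic"):
    """Wrap raw labeled score points in a ScoreCloud (for direct metric use)."""
    from .pca_core import ScoreCloud

    points = np.asarray(points, float)
    meta = pd.DataFrame({
        "well_id": [f"P{i:03d}" for i in range(len(points))],
        "sample_id": np.asarray(labels, dtype=str),
        "replicate": _replicate_indices(labels),
        "is_blank": False,
        "condition": condition,
    })
    explained = np.zeros(points.shape[1])
    loadings = np.eye(points.shape[1])
    return ScoreCloud(points, explained, loadings, meta)


def _replicate_indices(labels) -> list[int]:
    seen: dict[str, int] = {}
    out = []
    for lab in np.asarray(labels, dtype=str):
        seen[lab] = seen.get(lab, 0) + 1
        out.append(seen[lab])
    return out
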