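"""Synthetic two-class ultrasound-like texture phantoms.

Real TRUS patches are unavailable, so the pipeline is exercised on the
minimal standard B-mode texture model: a log-domain Gaussian Markov
random field modulating a mean echo level, multiplied by unit-mean
gamma speckle,

    I = clip( mu * exp(sigma * G) * S_L , 0, 255 ),   S_L ~ Gamma(L, 1/L)

where G is a unit-variance GMRF realization whose coefficient vector
theta differs between the two classes, sigma sets the log-echogenicity
texture amplitude, and L is the number of speckle "looks" (L = 1 is
fully developed speckle; larger L means more compounding/smoothing).

Each synthetic case (patient) gets its own RNG substream, and each
image its own child stream, so cases are exchangeable and the dataset
is fully deterministic given the master seed.  Patches default to
64 x 160 pixels, roughly the strip along a biopsy needle track.

This module emulates two-class textured 8-bit patches with case
structure; it does not attempt physically realistic ultrasound
simulation (no point-spread function, attenuation or shadowing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from trustex.data_io import NEGATIVE, POSITIVE, DatasetManifest, SampleRecord, write_manifest
from trustex.texture_features import gmrf_synthesize

DEFAULT_THETA_NEG = (0.05, 0.05, 0.0, 0.0)
DEFAULT_THETA_POS = (0.25, 0.25, 0.0, 0.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic two-class dataset."""

    n_cases_per_class: int = 20
    images_per_case: int = 5
    height: int = 64
    width: int = 160
    theta_neg: tuple = DEFAULT_THETA_NEG
    theta_pos: tuple = DEFAULT_THETA_POS
    nu: float = 1.0
    sigma_log: float = 0.3  # log-echogenicity texture amplitude
    looks: int = 8          # effective speckle looks (display-processed B-mode)
    mean_level: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.looks < 1:
            raise ValueError(f"looks must be >= 1, got {self.looks}")
        if self.images_per_case < 1 or self.n_cases_per_class < 1:
            raise ValueError("need at least one case and one image per case")

    @classmethod
    def two_class(cls, theta_gap: float, **kw) -> "PhantomConfig":
        """Classes separated by `theta_gap` on the two axial coefficients."""
        base = np.asarray(DEFAULT_THETA_NEG)
        pos = base + np.array([theta_gap, theta_gap, 0.0, 0.0])
        return cls(theta_neg=tuple(base), theta_pos=tuple(pos), **kw)


def speckle(img: np.ndarray, looks: int, seed=None) -> np.ndarray:
    """Multiplicative unit-mean gamma speckle: img * Gamma(L, 1/L) iid per pixel."""
    if looks < 1:
        raise ValueError(f"looks must be >= 1, got {looks}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.asarray(img, dtype=np.float64) * rng.gamma(looks, 1.0 / looks, size=np.shape(img))


def render_patch(theta, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """One 8-bit phantom patch for the given class coefficients."""
    g = gmrf_synthesize(theta, cfg.nu, (cfg.height, cfg.width), seed=rng)
    g = g / g.std()  # unit texture variance regardless of theta
    base = cfg.mean_level * np.exp(cfg.sigma_log * g)
    noisy = speckle(base, cfg.looks, seed=rng)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _iter_patches(cfg: PhantomConfig):
    """Yield (case_id, label, image_index, patch) deterministically."""
    master = np.random.SeedSequence(cfg.seed)
    classes = [(NEGATIVE, cfg.theta_neg), (POSITIVE, cfg.theta_pos)]
    case_streams = master.spawn(2 * cfg.n_cases_per_class)
    for ci, stream in enumerate(case_streams):
        label, theta = classes[ci % 2]
        case_id = f"case{ci:03d}"
        for ii, child in enumerate(stream.spawn(cfg.images_per_case)):
            yield case_id, label, ii, render_patch(theta, cfg, np.random.default_rng(child))


def generate_arrays(cfg: PhantomConfig):
    """In-memory dataset: (images, labels, case_ids), deterministic given cfg.seed."""
    images, labels, case_ids = [], [], []
    for case_id, label, _, patch in _iter_patches(cfg):
        images.append(patch)
        labels.append(label)
        case_ids.append(case_id)
    return images, np.array(labels), np.array(case_ids)


def generate_dataset(cfg: PhantomConfig, out_dir) -> DatasetManifest:
    """Write PNG patches plus manifest.csv; returns the manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    records = []
    for case_id, label, ii, patch in _iter_patches(cfg):
        name = f"{case_id}_{label[:3]}_{ii}.png"
        iio.imwrite(out_dir / name, patch)
        records.append(SampleRecord(str(out_dir / name), case_id, label))
    manifest = DatasetManifest(
        records=records,
        provenance=f"trustex.phantom seed={cfg.seed} "
        f"theta_neg={cfg.theta_neg} theta_pos={cfg.theta_pos} "
        f"L={cfg.looks} sigma={cfg.sigma_log}",
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
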