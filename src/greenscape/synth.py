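"""Seeded synthetic landscapes, drivers, transition pairs and masks.

The generator emulates the statistical structure the downstream stages
assume about real land-cover data, without any download:

* spatially autocorrelated multi-class maps with controlled class
  proportions (smoothed Gaussian field cut at proportion quantiles);
* driver layers statistically associated with class identity, with a
  signal-to-noise dial;
* a second time step drawn from a known transition matrix, optionally
  biased toward cells whose neighbors already hold the target class;
* contiguous restricted-area masks.

Every operation derives a dedicated RNG from ``(seed, op-name)`` so the
stages are independently reproducible: rerunning one generator never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from greenscape.grid import (
    GLOBELAND30,
    ClassScheme,
    DriverStack,
    LandCoverGrid,
    MaskGrid,
)

__all__ = [
    "SynthConfig",
    "gen_landscape",
    "gen_drivers",
    "gen_transition_pair",
    "gen_restricted_mask",
]

#: Default class proportions: a cultivated-land dominated landscape with a
#: large forest share and small grassland / wetland / water / artificial /
#: bare fractions, mirroring the composition of a north-temperate
#: agricultural municipality.
DEFAULT_PROPORTIONS = (0.49, 0.36, 0.08, 0.02, 0.02, 0.025, 0.005)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study region.

    ``transition_matrix`` rows are from-class transition probabilities per
    study interval; ``adjacency_bias`` b multiplies each probability by
    ``(1 + b * neighbor fraction of the target class)``, reproducing the
    spatial contagion of real land-cover change (b=0 recovers an i.i.d.
    per-cell Markov draw).
    """

    seed: int = 0
    shape: tuple[int, int] = (200, 200)
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    correlation_length: float = 8.0
    n_drivers: int = 6
    driver_snr: float = 5.0
    transition_matrix: np.ndarray | None = None
    adjacency_bias: float = 0.0
    restricted_fraction: float = 0.0
    scheme: ClassScheme = GLOBELAND30

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {props.sum()}, not 1")
        if (props < 0).any():
            raise ValueError("class proportions must be non-negative")
        if len(props) != self.scheme.n_classes:
            raise ValueError(
                f"{len(props)} proportions for {self.scheme.n_classes} classes"
            )
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, dtype=float)
            if tm.shape != (self.scheme.n_classes,) * 2:
                raise ValueError("transition matrix shape mismatch")
            if np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("transition matrix rows must sum to 1")
            if (tm < 0).any():
                raise ValueError("transition probabilities must be non-negative")
            self.transition_matrix = tm
        if not 0.0 <= self.restricted_fraction <= 1.0:
            raise ValueError("restricted_fraction must lie in [0, 1]")


def _rng(cfg: SynthConfig, op: str) -> np.random.Generator:
    # per-operation stream: stable across runs and across numpy versions
    return np.random.default_rng([cfg.seed, zlib.crc32(op.encode())])


def _smooth_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    field = rng.standard_normal(shape)
    if corr_len > 0:
        field = ndimage.gaussian_filter(field, sigma=corr_len, mode="reflect")
    return field


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def gen_landscape(cfg: SynthConfig) -> LandCoverGrid:
    """Spatially autocorrelated categorical map with exact class proportions.

    A Gaussian random field smoothed at ``correlation_length`` is rank-cut
    at the cumulative class proportions, so realized frequencies match the
    request to within one cell while neighboring cells remain correlated.
    """
    rng = _rng(cfg, "landscape")
    field = _smooth_field(rng, cfg.shape, cfg.correlation_length)
    n = field.size
    counts = _largest_remainder(np.asarray(cfg.class_proportions), n)
    order = np.argsort(field, axis=None, kind="stable")
    flat = np.empty(n, dtype=np.int64)
    codes = cfg.scheme.codes
    start = 0
    for k, c in enumerate(counts):
        flat[order[start : start + c]] = codes[k]
        start += c
    return LandCoverGrid(values=flat.reshape(cfg.shape), scheme=cfg.scheme)


def gen_drivers(grid: LandCoverGrid, cfg: SynthConfig) -> DriverStack:
    """Driver layers whose values carry class identity at a chosen SNR.

    Each driver is a per-class mean (drawn once per class per driver)
    plus spatially smoothed unit-variance noise scaled by ``1/driver_snr``.
    ``driver_snr = inf`` gives drivers that are deterministic functions of
    class; ``driver_snr = 0`` gives pure noise, independent of class.
    """
    if cfg.n_drivers < 1:
        raise ValueError("n_drivers must be >= 1")
    rng = _rng(cfg, "drivers")
    idx = grid.class_indices()
    k = grid.scheme.n_classes
    layers: list[tuple[str, np.ndarray]] = []
    for d in range(cfg.n_drivers):
        means = rng.uniform(0.0, 1.0, size=k)
        noise = _smooth_field(rng, grid.shape, 2.0)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        if cfg.driver_snr == 0:
            layer = noise
        elif np.isinf(cfg.driver_snr):
            layer = means[np.clip(idx, 0, None)].astype(float)
        else:
            layer = means[np.clip(idx, 0, None)] + noise / cfg.driver_snr
        layer = layer.copy()
        layer[idx < 0] = np.nan
        layers.append((f"driver_{d}", layer))
    return DriverStack(layers=layers, normalized=False)


def _neighbor_fraction(idx: np.ndarray, n_classes: int) -> np.ndarray:
    """(rows, cols, k) fraction of each class in the 3x3 window, center excluded."""
    rows, cols = idx.shape
    frac = np.empty((rows, cols, n_classes), dtype=float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    denom = ndimage.convolve(
        np.ones_like(idx, dtype=float), kernel, mode="constant", cval=0.0
    )
    for k in range(n_classes):
        onehot = (idx == k).astype(float)
        frac[:, :, k] = ndimage.convolve(onehot, kernel, mode="constant", cval=0.0)
    frac /= denom[:, :, None]
    return frac


def gen_transition_pair(grid: LandCoverGrid, cfg: SynthConfig) -> LandCoverGrid:
    """Second time step drawn from ``cfg.transition_matrix``.

    Cell transition probabilities are ``P[i, j] * (1 + adjacency_bias *
    neighbor fraction of j)``, renormalized per cell.  With bias 0 the
    empirical transition frequencies converge to ``P``; with an identity
    matrix the map is returned unchanged for any bias.
    """
    if cfg.transition_matrix is None:
        raise ValueError("cfg.transition_matrix is required")
    P = cfg.transition_matrix
    rng = _rng(cfg, "transition")
    idx = grid.class_indices()
    k = grid.scheme.n_classes
    probs = P[np.clip(idx, 0, None)]  # (rows, cols, k)
    if cfg.adjacency_bias > 0:
        frac = _neighbor_fraction(idx, k)
        probs = probs * (1.0 + cfg.adjacency_bias * frac)
    total = probs.sum(axis=-1, keepdims=True)
    probs = probs / total
    u = rng.random(idx.shape)
    cum = np.cumsum(probs, axis=-1)
    new_idx = (u[..., None] >= cum).sum(axis=-1)
    out = grid.scheme.codes[new_idx]
    out[idx < 0] = grid.nodata
    return grid.copy_with(out)


def gen_restricted_mask(grid: LandCoverGrid, cfg: SynthConfig) -> MaskGrid:
    """Contiguous restricted blobs covering ``restricted_fraction`` of cells.

    A smoothed field is rank-thresholded, so coverage is exact to one cell
    and the restricted area forms connected patches, like rasterized
    nature-reserve polygons.
    """
    frac = cfg.restricted_fraction
    if frac <= 0.0:
        return MaskGrid(values=np.zeros(grid.shape, dtype=bool))
    if frac >= 1.0:
        return MaskGrid(values=np.ones(grid.shape, dtype=bool))
    rng = _rng(cfg, "mask")
    field = _smooth_field(rng, grid.shape, max(cfg.correlation_length, 2.0))
    n_true = int(round(frac * field.size))
    order = np.argsort(field, axis=None, kind="stable")
    mask = np.zeros(field.size, dtype=bool)
    mask[order[-n_true:]] = True
    return MaskGrid(values=mask.reshape(grid.shape))
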