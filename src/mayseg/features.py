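"""HOG descriptors and a pre-activation residual embedding, both from scratch.

HOG (histogram of oriented gradients): gradient magnitude and unsigned
orientation per pixel, magnitude-weighted orientation histograms per cell
with linear interpolation between the two nearest bin centers, L2-hys
normalization per 2x2-cell block, all block vectors concatenated.  The
descriptor is then padded with zeros or truncated to a fixed output
dimension (1236 by default) so the feature count is an interface contract
independent of image size.

The deep embedding is a small ResNet-V2-style network: per-channel
normalization -> ReLU -> 3x3 convolution, twice, with a parameter-free
identity shortcut around each block, followed by global average pooling.
Weights are seeded random by default (the untrained embedding is a fixed
random projection with spatial structure); a user-supplied ``.npz`` weight
file can be loaded instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.transform import resize as _resize

__all__ = [
    "FeatureSource",
    "FeatureVector",
    "HOGConfig",
    "ResidualBackboneSpec",
    "gradients",
    "cell_histograms",
    "hog_features",
    "ResidualBackbone",
    "deep_features",
]


class FeatureSource(str, Enum):
    HOG = "hog"
    DEEP = "deep"
    FUSED = "fused"


@dataclass(frozen=True)
class FeatureVector:
    """1-D real feature vector tagged with its provenance."""

    values: np.ndarray
    source: FeatureSource

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HOGConfig:
    """HOG layout parameters.

    ``block_stride`` is in pixels; with the default 4-pixel cells the
    default stride of 4 advances one cell per block step.  ``target_dim``
    fixes the emitted descriptor length by zero-pad / truncate.
    """

    n_bins: int = 9
    cell_size: int = 4
    block_size: int = 2  # cells per block side
    block_stride: int = 4  # pixels
    resize_to: int = 32
    signed: bool = False  # unsigned: orientations span [0, 180)
    target_dim: int = 1236
    epsilon: float = 1e-6
    hys_clip: float = 0.2

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.target_dim < 1:
            raise ValueError("n_bins and target_dim must be positive")
        if self.signed:
            raise NotImplementedError("only the unsigned 0-180 degree range is supported")
        if self.block_stride % self.cell_size != 0:
            raise ValueError("block_stride must be a whole number of cells")

    @property
    def angle_range(self) -> float:
        return 180.0


def gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and unsigned orientation in degrees.

    Central differences in the interior, one-sided at the borders.
    ``m = sqrt(ix^2 + iy^2)``; orientation = atan(iy/ix) folded to
    [0, 180), with vertical gradients at 90 and zero-magnitude pixels
    assigned orientation 0 by convention.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    iy, ix = np.gradient(image)
    magnitude = np.hypot(ix, iy)
    orientation = np.degrees(np.arctan2(iy, ix)) % 180.0
    orientation[orientation >= 180.0] = 0.0
    orientation[magnitude == 0] = 0.0
    return magnitude, orientation


def cell_histograms(image: np.ndarray, config: HOGConfig | None = None) -> np.ndarray:
    """Raw (un-normalized) per-cell orientation histograms.

    Returns an array of shape ``(n_cells_y, n_cells_x, n_bins)``.  Each
    pixel votes its gradient magnitude into the two orientation bins
    nearest its angle, linearly interpolated; bin centers are at
    ``(k + 0.5) * 180 / n_bins`` and interpolation wraps around.
    """
    if config is None:
        config = HOGConfig()
    magnitude, orientation = gradients(image)
    c = config.cell_size
    ny, nx = image.shape[0] // c, image.shape[1] // c
    magnitude = magnitude[: ny * c, : nx * c]
    orientation = orientation[: ny * c, : nx * c]

    bin_width = config.angle_range / config.n_bins
    pos = orientation / bin_width - 0.5  # fractional bin coordinate
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    hi = (lo + 1) % config.n_bins
    lo = lo % config.n_bins
    w_lo = magnitude * (1.0 - frac)
    w_hi = magnitude * frac

    hist = np.zeros((ny, nx, config.n_bins))
    cy = np.arange(ny * c) // c
    cx = np.arange(nx * c) // c
    cell_y = np.repeat(cy, nx * c).reshape(ny * c, nx * c)
    cell_x = np.tile(cx, (ny * c, 1))
    np.add.at(hist, (cell_y.ravel(), cell_x.ravel(), lo.ravel()), w_lo.ravel())
    np.add.at(hist, (cell_y.ravel(), cell_x.ravel(), hi.ravel()), w_hi.ravel())
    return hist


def _l2_hys(block: np.ndarray, eps: float, clip: float) -> np.ndarray:
    v = block / np.sqrt((block**2).sum() + eps**2)
    v = np.minimum(v, clip)
    return v / np.sqrt((v**2).sum() + eps**2)


def hog_features(image: np.ndarray, config: HOGConfig | None = None) -> FeatureVector:
    """Full HOG descriptor of fixed length ``config.target_dim``."""
    if config is None:
        config = HOGConfig()
    image = np.asarray(image, dtype=float)
    if image.shape != (config.resize_to, config.resize_to):
        image = _resize(image, (config.resize_to, config.resize_to), anti_aliasing=True)
    hist = cell_histograms(image, config)
    ny, nx, _ = hist.shape
    b = config.block_size
    stride_cells = config.block_stride // config.cell_size
    blocks = []
    for by in range(0, ny - b + 1, stride_cells):
        for bx in range(0, nx - b + 1, stride_cells):
            blocks.append(_l2_hys(hist[by : by + b, bx : bx + b].ravel(), config.epsilon, config.hys_clip))
    desc = np.concatenate(blocks) if blocks else np.zeros(0)
    if len(desc) >= config.target_dim:
        desc = desc[: config.target_dim]
    else:
        desc = np.pad(desc, (0, config.target_dim - len(desc)))
    return FeatureVector(values=desc, source=FeatureSource.HOG)


@dataclass(frozen=True)
class ResidualBackboneSpec:
    """Architecture of the seeded residual embedding network.

    ``channels`` is the constant width of every block; the embedding is the
    global average pool over space, so ``embedding_dim == channels``.
    """

    n_blocks: int = 3
    channels: int = 64
    input_side: int = 32
    seed: int = 0
    pretrained: bool = False
    weight_file: str | None = None

    @property
    def embedding_dim(self) -> int:
        return self.channels


def _conv3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution via im2col; x is (C, H, W), w is
    (C_out, C_in, 3, 3)."""
    c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = np.empty((c * 9, h * wd))
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[k * c : (k + 1) * c] = xp[:, dy : dy + h, dx : dx + wd].reshape(c, -1)
            k += 1
    wmat = w.transpose(0, 2, 3, 1).reshape(w.shape[0], -1)  # (C_out, 9*C_in)
    # reorder cols to match (dy, dx, c) layout of wmat
    return (wmat @ cols).reshape(w.shape[0], h, wd)


def _channel_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    return (x - mu) / (sd + eps)


class ResidualBackbone:
    """Pre-activation residual network over a single-channel image.

    The stem tiles the contrast-normalized input across all channels
    (parameter-free), each block computes
    ``x + conv(relu(norm(conv(relu(norm(x))))))`` with an identity
    shortcut, and the embedding is the spatial mean per channel.  With all
    convolution weights zero every block is the identity map.
    """

    def __init__(self, spec: ResidualBackboneSpec):
        self.spec = spec
        if spec.pretrained:
            if not spec.weight_file:
                raise ValueError("pretrained=True requires a weight_file")
            data = np.load(spec.weight_file)
            self.weights = [
                (data[f"block{i}_w1"], data[f"block{i}_w2"]) for i in range(spec.n_blocks)
            ]
        else:
            rng = np.random.default_rng(spec.seed)
            c = spec.channels
            scale = np.sqrt(2.0 / (9 * c))
            self.weights = [
                (
                    rng.normal(0.0, scale, size=(c, c, 3, 3)),
                    rng.normal(0.0, scale, size=(c, c, 3, 3)),
                )
                for _ in range(spec.n_blocks)
            ]

    def embed(self, image: np.ndarray) -> np.ndarray:
        spec = self.spec
        image = np.asarray(image, dtype=float)
        if image.shape != (spec.input_side, spec.input_side):
            image = _resize(image, (spec.input_side, spec.input_side), anti_aliasing=True)
        sd = image.std()
        x0 = (image - image.mean()) / (sd if sd > 0 else 1.0)
        x = np.broadcast_to(x0, (spec.channels, *x0.shape)).copy()
        for w1, w2 in self.weights:
            h = _conv3x3(np.maximum(_channel_norm(x), 0.0), w1)
            h = _conv3x3(np.maximum(_channel_norm(h), 0.0), w2)
            x = x + h
        return x.mean(axis=(1, 2))


def deep_features(image: np.ndarray, spec: ResidualBackboneSpec | None = None) -> FeatureVector:
    """Residual-network embedding of an image (deterministic per seed)."""
    if spec is None:
        spec = ResidualBackboneSpec()
    return FeatureVector(values=ResidualBackbone(spec).embed(image), source=FeatureSource.DEEP)
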