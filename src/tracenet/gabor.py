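"""Gabor-filter V1 front end.

A bank of zero-mean, unit-norm Gabor filters is evaluated on a regular
sampling grid over the image; positive and negative filter responses are
half-wave rectified into separate non-negative channels, emulating ON/OFF
pairs of simple cells. The resulting firing-rate vector is the input to
layer 1 of the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .stimuli import BACKGROUND

__all__ = ["GaborBankSpec", "EncodingLayout", "GaborBank", "InputEncoding",
           "build_gabor_bank", "encode_image", "encode_set"]


@dataclass(frozen=True)
class GaborBankSpec:
    """Parameters of the V1 filter bank.

    ``sigma_factor`` sets the Gaussian envelope width as sigma_factor /
    frequency pixels, i.e. a constant number of cycles under the envelope at
    every scale. The sampling grid places one filter position every
    ``grid_stride`` pixels.
    """

    image_size: int = 128
    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    spatial_frequencies: tuple = (0.35, 0.25, 0.125)
    phases: tuple = (0.0, 90.0)
    sigma_factor: float = 0.5
    grid_stride: int = 8

    def validate(self) -> None:
        if not self.orientations or not self.spatial_frequencies or not self.phases:
            raise ValueError("orientations, frequencies and phases must be non-empty")
        for f in self.spatial_frequencies:
            if not 0 < f <= 0.5:
                raise ValueError(f"spatial frequency {f} outside (0, 0.5] cycles/px")
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be positive")
        for f in self.spatial_frequencies:
            if self.sigma_factor / f < 0.75:
                raise ValueError(
                    f"degenerate envelope: sigma {self.sigma_factor / f:.2f} px "
                    f"at frequency {f}"
                )
        if self.grid_stride < 1 or self.grid_stride > self.image_size:
            raise ValueError("grid_stride must be in [1, image_size]")


class EncodingLayout:
    """Mapping position x orientation x frequency x phase x sign -> index.

    Channels at one grid position occupy a contiguous block:
    flat_index = position_index * channels_per_position + channel.
    """

    def __init__(self, spec: GaborBankSpec):
        stride = spec.grid_stride
        coords = np.arange(stride // 2, spec.image_size, stride)
        self.grid_shape = (len(coords), len(coords))
        gy, gx = np.meshgrid(coords, coords, indexing="ij")
        self.positions = np.column_stack([gy.ravel(), gx.ravel()])  # (n_pos, 2) row,col
        self.n_orient = len(spec.orientations)
        self.n_freq = len(spec.spatial_frequencies)
        self.n_phase = len(spec.phases)
        self.channels_per_position = self.n_orient * self.n_freq * self.n_phase * 2
        self.length = len(self.positions) * self.channels_per_position

    def channel(self, orient: int, freq: int, phase: int, sign: int) -> int:
        return ((orient * self.n_freq + freq) * self.n_phase + phase) * 2 + sign

    def index(self, position: int, orient: int, freq: int, phase: int, sign: int) -> int:
        return position * self.channels_per_position + self.channel(
            orient, freq, phase, sign
        )


class GaborBank:
    """Realised filter bank: one zero-mean unit-norm kernel per
    (orientation, frequency, phase) triple, shared across grid positions."""

    def __init__(self, spec: GaborBankSpec):
        spec.validate()
        self.spec = spec
        self.layout = EncodingLayout(spec)
        self.kernels = []  # [(orient_idx, freq_idx, phase_idx, kernel)]
        for oi, theta_deg in enumerate(spec.orientations):
            for fi, freq in enumerate(spec.spatial_frequencies):
                sigma = spec.sigma_factor / freq
                for pi, phase_deg in enumerate(spec.phases):
                    k = np.real(
                        gabor_kernel(
                            frequency=freq,
                            theta=np.deg2rad(theta_deg),
                            sigma_x=sigma,
                            sigma_y=sigma,
                            offset=np.deg2rad(phase_deg),
                            n_stds=3,
                        )
                    ).astype(np.float64)
                    k -= k.mean()
                    norm = np.linalg.norm(k)
                    if norm < 1e-12:
                        raise ValueError(
                            "degenerate kernel (zero norm) for "
                            f"freq={freq}, phase={phase_deg}"
                        )
                    k /= norm
                    self.kernels.append((oi, fi, pi, k))

    @property
    def n_filters(self) -> int:
        """Number of filters: grid positions x orientations x freqs x phases."""
        return len(self.layout.positions) * len(self.kernels)


@dataclass
class InputEncoding:
    """Non-negative V1-like firing-rate vector for one image."""

    rates: np.ndarray
    layout: EncodingLayout

    def __post_init__(self):
        if np.any(self.rates < 0):
            raise ValueError("encoding rates must be non-negative")


def build_gabor_bank(spec: GaborBankSpec) -> GaborBank:
    """Construct the filter bank (deterministic in the spec)."""
    return GaborBank(spec)


def _raw_responses(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Signed filter responses, shape (n_pos, n_orient*n_freq*n_phase).

    response = sum over pixels of kernel * (image - background), i.e. spatial
    correlation of the contrast image with each kernel, sampled at the grid.
    """
    img = np.asarray(image, dtype=np.float64) - BACKGROUND
    pos = bank.layout.positions
    n_kernel_ch = bank.layout.channels_per_position // 2
    out = np.empty((len(pos), n_kernel_ch))
    for oi, fi, pi, k in bank.kernels:
        # correlation = convolution with the doubly flipped kernel
        full = fftconvolve(img, k[::-1, ::-1], mode="same")
        ch = (oi * bank.layout.n_freq + fi) * bank.layout.n_phase + pi
        out[:, ch] = full[pos[:, 0], pos[:, 1]]
    return out


def encode_image(image: np.ndarray, bank: GaborBank) -> InputEncoding:
    """Encode one image as a non-negative firing-rate vector.

    Positive and negative parts of each filter response occupy separate
    channels (half-wave rectification).
    """
    if image.shape != (bank.spec.image_size, bank.spec.image_size):
        raise ValueError(
            f"image shape {image.shape} does not match bank image_size "
            f"{bank.spec.image_size}"
        )
    raw = _raw_responses(image, bank)  # (n_pos, C/2)
    n_pos, half = raw.shape
    rates = np.zeros((n_pos, half, 2))
    rates[:, :, 0] = np.maximum(raw, 0.0)
    rates[:, :, 1] = np.maximum(-raw, 0.0)
    return InputEncoding(rates=rates.reshape(-1), layout=bank.layout)


def encode_set(stimulus_set, bank: GaborBank) -> np.ndarray:
    """Encode every image of a StimulusSet; rows follow item order."""
    return np.stack([encode_image(im, bank).rates for im, _ in stimulus_set.items])
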