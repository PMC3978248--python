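"""Four-layer convergent competitive hierarchy.

Each layer is a grid of neurons, every neuron receiving ``fan_in`` synapses
from a localized disc of the previous layer (the Gabor encoding grid for
layer 1). A presentation is processed as

    linear response -> short-range lateral inhibition -> contrast sigmoid

where the sigmoid threshold sits at a percentile of the layer's current
activations, enforcing a stable firing sparseness (soft competition).
Forward processing never modifies weights.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import convolve as nd_convolve
from scipy.special import expit

__all__ = [
    "LayerConfig",
    "Layer",
    "Network",
    "init_network",
    "linear_response",
    "inhibition_kernel",
    "lateral_inhibition",
    "contrast_sigmoid",
    "forward_pass",
    "default_layer_configs",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class LayerConfig:
    grid_width: int
    grid_height: int
    fan_in: int
    convergence_radius: float  # in units of the *previous* grid
    inhibition_sigma: float = 1.5
    inhibition_strength: float = 0.9
    sparseness_percentile: float = 10.0  # % of neurons intended to fire strongly
    sigmoid_slope: float = 30.0

    def validate(self) -> None:
        if self.fan_in < 1:
            raise ValueError("fan_in must be >= 1")
        if self.convergence_radius <= 0:
            raise ValueError("convergence_radius must be positive")
        if not 0 < self.sparseness_percentile < 100:
            raise ValueError("sparseness_percentile must be in (0, 100)")

    @property
    def n_neurons(self) -> int:
        return self.grid_width * self.grid_height


class Layer:
    """Weights + connectivity of one competitive layer."""

    def __init__(self, config: LayerConfig, weights: np.ndarray,
                 connectivity: np.ndarray):
        self.config = config
        self.weights = weights  # (n_neurons, fan_in), unit-norm rows, >= 0
        self.connectivity = connectivity  # (n_neurons, fan_in) presyn indices

    def check_invariants(self) -> None:
        if np.any(self.weights < 0):
            raise AssertionError("negative synaptic weight")
        norms = np.linalg.norm(self.weights, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise AssertionError("weight rows not unit-norm")


class Network:
    """Ordered stack of four layers plus the input-grid geometry."""

    def __init__(self, layers, configs, input_grid_shape, input_channels, seed):
        self.layers = list(layers)
        self.configs = list(configs)
        self.input_grid_shape = tuple(input_grid_shape)
        self.input_channels = int(input_channels)
        self.seed = seed

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _grid_centers(n_post_h, n_post_w, n_pre_h, n_pre_w):
    """Presynaptic-grid coordinates of each postsynaptic neuron's center."""
    rows = (np.arange(n_post_h) + 0.5) * n_pre_h / n_post_h - 0.5
    cols = (np.arange(n_post_w) + 0.5) * n_pre_w / n_post_w - 0.5
    R, C = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([R.ravel(), C.ravel()])


def _sample_connectivity(rng, config, pre_shape, pre_channels):
    """Fan-in indices for every neuron, sampled without replacement from the
    channels of presynaptic positions within the convergence disc."""
    n_pre_h, n_pre_w = pre_shape
    centers = _grid_centers(config.grid_height, config.grid_width,
                            n_pre_h, n_pre_w)
    pre_r, pre_c = np.meshgrid(np.arange(n_pre_h), np.arange(n_pre_w),
                               indexing="ij")
    pre_pos = np.column_stack([pre_r.ravel(), pre_c.ravel()])
    conn = np.empty((config.n_neurons, config.fan_in), dtype=np.int64)
    for i, ctr in enumerate(centers):
        d2 = ((pre_pos - ctr) ** 2).sum(axis=1)
        pos_in = np.flatnonzero(d2 <= config.convergence_radius**2)
        pool = (pos_in[:, None] * pre_channels
                + np.arange(pre_channels)[None, :]).ravel()
        if len(pool) < config.fan_in:
            raise ValueError(
                f"fan_in {config.fan_in} exceeds {len(pool)} available sources "
                f"within radius {config.convergence_radius} for neuron {i}"
            )
        conn[i] = rng.choice(pool, size=config.fan_in, replace=False)
    return conn


def init_network(configs, input_grid_shape, input_channels, seed=0) -> Network:
    """Build the hierarchy: localized random connectivity, small positive
    random weights normalized to unit Euclidean norm per neuron."""
    rng = np.random.default_rng(seed)
    layers = []
    pre_shape = tuple(input_grid_shape)
    pre_channels = input_channels
    for config in configs:
        config.validate()
        conn = _sample_connectivity(rng, config, pre_shape, pre_channels)
        w = rng.uniform(0.0, 1.0, size=conn.shape)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        layers.append(Layer(config, w, conn))
        pre_shape = (config.grid_height, config.grid_width)
        pre_channels = 1
    return Network(layers, configs, input_grid_shape, input_channels, seed)


def linear_response(layer: Layer, presyn_rates: np.ndarray) -> np.ndarray:
    """activation_i = sum_j w_ij * x_j over neuron i's synapses."""
    x = np.asarray(presyn_rates, dtype=np.float64)
    return np.einsum("nf,nf->n", layer.weights, x[layer.connectivity])


def inhibition_kernel(sigma: float, strength: float) -> np.ndarray:
    """Center-surround kernel: unit center minus a Gaussian surround of unit
    mass scaled by ``strength`` (center pixel excluded from the surround)."""
    radius = max(1, int(np.ceil(3 * sigma)))
    ax = np.arange(-radius, radius + 1)
    X, Y = np.meshgrid(ax, ax)
    g = np.exp(-(X**2 + Y**2) / (2 * sigma**2))
    g[radius, radius] = 0.0
    g /= g.sum()
    k = -strength * g
    k[radius, radius] += 1.0
    return k


def lateral_inhibition(activations: np.ndarray, sigma: float,
                       strength: float, kernel: np.ndarray | None = None
                       ) -> np.ndarray:
    """Convolve the activation grid with the center-surround kernel
    (zero padding at the borders)."""
    if kernel is None:
        kernel = inhibition_kernel(sigma, strength)
    return nd_convolve(activations, kernel, mode="constant", cval=0.0)


def contrast_sigmoid(activations: np.ndarray, sparseness_percentile: float,
                     slope: float) -> np.ndarray:
    """Map activations to rates in [0, 1] with a logistic whose threshold is
    the (100 - sparseness)-th percentile of the current activations.

    Activations are rescaled by their maximum before thresholding so the
    slope is dimensionless. A silent layer (max activation <= 0) stays
    silent.
    """
    a = np.asarray(activations, dtype=np.float64)
    m = a.max()
    if m <= 0:
        return np.zeros_like(a)
    a = a / m
    theta = np.percentile(a, 100.0 - sparseness_percentile)
    return expit(slope * (a - theta))


def layer_response(layer: Layer, presyn_rates: np.ndarray,
                   kernel: np.ndarray | None = None) -> np.ndarray:
    """One layer's full transform of its presynaptic rates."""
    c = layer.config
    a = linear_response(layer, presyn_rates)
    grid = a.reshape(c.grid_height, c.grid_width)
    g = lateral_inhibition(grid, c.inhibition_sigma, c.inhibition_strength,
                           kernel=kernel)
    return contrast_sigmoid(g.ravel(), c.sparseness_percentile, c.sigmoid_slope)


def forward_pass(network: Network, encoding_rates: np.ndarray,
                 up_to_layer: int = 4) -> list:
    """Rates at layers 1..up_to_layer for one input encoding (no learning)."""
    if not 1 <= up_to_layer <= network.n_layers:
        raise ValueError(f"up_to_layer must be in [1, {network.n_layers}]")
    rates = []
    x = np.asarray(encoding_rates, dtype=np.float64)
    for layer in network.layers[:up_to_layer]:
        x = layer_response(layer, x)
        rates.append(x)
    return rates


def receptive_field_union(network: Network, up_to_layer: int = 4) -> np.ndarray:
    """Input positions reachable from any neuron of the given layer
    (composed connectivity closure). Returns a boolean mask over input
    positions."""
    n_inputs = (network.input_grid_shape[0] * network.input_grid_shape[1]
                * network.input_channels)
    # compose connectivity downwards from the top layer
    reach = np.ones(network.layers[up_to_layer - 1].config.n_neurons, dtype=bool)
    for li in range(up_to_layer - 1, 0, -1):
        conn = network.layers[li].connectivity
        pre = np.unique(conn[np.flatnonzero(reach)])
        reach = np.zeros(network.layers[li - 1].config.n_neurons, dtype=bool)
        reach[pre] = True
    conn0 = network.layers[0].connectivity
    inputs = np.unique(conn0[np.flatnonzero(reach)])
    covered = np.zeros(n_inputs, dtype=bool)
    covered[inputs] = True
    return covered


def default_layer_configs(input_grid_shape, grid: int = 24, fan_in: int = 100):
    """Layer configurations with convergence radii increasing so the top
    layer spans the whole input grid."""
    gh, gw = input_grid_shape
    r1 = max(2.0, 0.28 * max(gh, gw))
    # upper-layer fan-in is limited by the sources available inside the
    # convergence disc at grid corners
    upper = max(10, int(0.6 * fan_in))
    return [
        LayerConfig(grid, grid, fan_in, convergence_radius=r1),
        LayerConfig(grid, grid, upper, convergence_radius=0.56 * grid),
        LayerConfig(grid, grid, upper, convergence_radius=0.69 * grid),
        LayerConfig(grid, grid, upper, convergence_radius=0.88 * grid),
    ]


def save_network(network: Network, path) -> None:
    """Serialize the hierarchy to a compressed .npz container."""
    payload = {"seed": np.asarray(network.seed),
               "input_grid_shape": np.asarray(network.input_grid_shape),
               "input_channels": np.asarray(network.input_channels),
               "n_layers": np.asarray(network.n_layers)}
    for i, layer in enumerate(network.layers):
        payload[f"w{i}"] = layer.weights
        payload[f"c{i}"] = layer.connectivity
        cfg = asdict(layer.config)
        payload[f"cfg{i}_keys"] = np.asarray(list(cfg.keys()))
        payload[f"cfg{i}_vals"] = np.asarray([float(v) for v in cfg.values()])
    np.savez_compressed(path, **payload)


def load_network(path) -> Network:
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n_layers"])
        layers, configs = [], []
        for i in range(n):
            keys = [str(k) for k in z[f"cfg{i}_keys"]]
            vals = z[f"cfg{i}_vals"]
            kwargs = dict(zip(keys, vals))
            for ik in ("grid_width", "grid_height", "fan_in"):
                kwargs[ik] = int(kwargs[ik])
            config = LayerConfig(**kwargs)
            layers.append(Layer(config, z[f"w{i}"], z[f"c{i}"]))
            configs.append(config)
        return Network(layers, configs,
                       tuple(int(v) for v in z["input_grid_shape"]),
                       int(z["input_channels"]), int(z["seed"]))
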