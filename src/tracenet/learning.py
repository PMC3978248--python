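"""Trace and Hebbian synaptic plasticity with competitive weight
renormalization.

The trace rule replaces the postsynaptic firing rate of the plain Hebbian
update with an exponentially decaying running average (the trace) of recent
rates,

    trace(t) = (1 - eta) * y(t) + eta * trace(t-1)
    dw_ij    = alpha * trace_i(t) * x_j,

which binds together stimuli presented close together in time. At eta = 0
the rule reduces exactly to the Hebbian update. Traces are reset to zero at
every group boundary of the presentation schedule so temporal binding does
not leak between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, layer_response, inhibition_kernel

__all__ = [
    "LearningParams",
    "update_trace",
    "reset_trace",
    "apply_learning",
    "renormalize_weights",
    "train_network",
]


@dataclass
class LearningParams:
    rule: str = "trace"  # "trace" or "hebb"
    alpha: float = 0.3  # learning rate, scaled per layer by alpha_layer_scale
    trace_eta: float = 0.8
    epochs_per_layer: int = 50
    reset_trace_at_group_boundary: bool = True
    alpha_layer_scale: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.rule not in ("trace", "hebb"):
            raise ValueError("rule must be 'trace' or 'hebb'")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.trace_eta < 1.0:
            raise ValueError("trace_eta must lie in [0, 1)")

    def alpha_for(self, layer_index: int) -> float:
        return self.alpha * self.alpha_layer_scale[layer_index]


def update_trace(trace: np.ndarray, rates: np.ndarray, eta: float) -> np.ndarray:
    """trace <- (1 - eta) * rates + eta * trace."""
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta must lie in [0, 1)")
    return (1.0 - eta) * np.asarray(rates, dtype=np.float64) + eta * trace


def reset_trace(trace: np.ndarray) -> np.ndarray:
    """Zero every neuron's trace (idempotent)."""
    return np.zeros_like(trace)


def renormalize_weights(weights: np.ndarray) -> np.ndarray:
    """Scale each neuron's weight vector to unit Euclidean norm, in place."""
    norms = np.linalg.norm(weights, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot renormalize a zero-norm weight vector")
    weights /= norms
    return weights


def apply_learning(weights: np.ndarray, connectivity: np.ndarray,
                   presyn_rates: np.ndarray, post_signal: np.ndarray,
                   alpha: float) -> np.ndarray:
    """Associative update on existing synapses, then renormalization.

    dw_ij = alpha * post_i * x_j; with ``post_signal`` the trace this is the
    trace rule, with the instantaneous rates it is the pure Hebbian control.
    Modifies ``weights`` in place and returns it.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    post = np.asarray(post_signal, dtype=np.float64)
    if np.all(post == 0):
        return weights
    x = np.asarray(presyn_rates, dtype=np.float64)
    weights += alpha * post[:, None] * x[connectivity]
    return renormalize_weights(weights)


def train_network(network: Network, schedule, params: LearningParams,
                  encodings: np.ndarray, seed: int = 0,
                  log=None) -> Network:
    """Train the hierarchy layer by layer on a presentation schedule.

    Layers are trained sequentially from the bottom; within a layer, each
    epoch presents the schedule's groups in fixed order with a fresh random
    permutation of the images inside every group, resetting the trace at each
    group boundary. Only the layer currently being trained is updated.
    Deterministic given the seed.

    ``encodings`` is an (n_images, encoding_length) array indexed by the
    stimulus indices the schedule refers to. ``log``, if given, is a list
    that receives one text line per (layer, epoch, group) presentation block.
    """
    rng = np.random.default_rng(seed)
    n_images = len(encodings)
    for group in schedule.groups:
        for idx in group:
            if not 0 <= idx < n_images:
                raise IndexError(f"schedule references missing stimulus {idx}")

    presyn = np.asarray(encodings, dtype=np.float64)
    for li, layer in enumerate(network.layers):
        alpha = params.alpha_for(li)
        kernel = inhibition_kernel(layer.config.inhibition_sigma,
                                   layer.config.inhibition_strength)
        trace = np.zeros(layer.config.n_neurons)
        for epoch in range(params.epochs_per_layer):
            for gi, group in enumerate(schedule.groups):
                if params.reset_trace_at_group_boundary:
                    trace = reset_trace(trace)
                order = rng.permutation(len(group))
                if log is not None:
                    log.append(
                        f"layer={li + 1} epoch={epoch} group={gi} "
                        f"reset={params.reset_trace_at_group_boundary} "
                        f"order={','.join(str(group[o]) for o in order)}"
                    )
                for o in order:
                    x = presyn[group[o]]
                    y = layer_response(layer, x, kernel=kernel)
                    if params.rule == "trace":
                        trace = update_trace(trace, y, params.trace_eta)
                        post = trace
                    else:
                        post = y
                    apply_learning(layer.weights, layer.connectivity, x,
                                   post, alpha)
        # freeze this layer: its outputs become the next layer's inputs
        presyn = np.stack([layer_response(layer, presyn[i], kernel=kernel)
                           for i in range(n_images)])
    return network
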