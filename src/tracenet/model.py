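"""Model/Results interface to the trace-learning hierarchy.

``TraceNetModel`` bundles a stimulus set, the V1 encoding, the four-layer
competitive hierarchy and a presentation schedule; ``fit()`` trains the
hierarchy layer by layer and returns a ``TraceNetResults`` carrying the
trained network, the layer-4 response matrix, single- and multiple-cell
information, decoding accuracy and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np

from . import gabor as gb
from . import info as it
from . import network as nw
from . import protocols as pr
from .learning import LearningParams, train_network

__all__ = ["TraceNetModel", "TraceNetResults", "population_responses"]


def population_responses(network, encodings, layer: int = 4) -> np.ndarray:
    """Top-layer rate vector per image: (n_images, n_cells)."""
    return np.stack(
        [nw.forward_pass(network, e, up_to_layer=layer)[-1] for e in encodings]
    )


class TraceNetModel:
    """Trace-learning hierarchical network over a factorial stimulus set.

    Parameters
    ----------
    stimulus_set : StimulusSet
        Factorial identity x deformation x view corpus.
    mode : {'object', 'deformation'}
        Temporal grouping of the training schedule; the experimental
        manipulation. Object mode groups all transforms of one identity,
        deformation mode all identities/views of one deformation.
    rule : {'trace', 'hebb'}
        Synaptic rule; 'hebb' is the purely associative control.
    gabor_spec, layer_configs, learning_params
        Optional overrides; sensible desk-scale defaults otherwise.
    normalize_inputs : bool
        Normalize each V1 encoding to unit Euclidean norm (firing-rate
        normalization) before it reaches layer 1.
    seed : int
        Controls connectivity/weight initialisation and presentation order.
    """

    def __init__(self, stimulus_set, mode: str = "object", rule: str = "trace",
                 gabor_spec=None, layer_configs=None, learning_params=None,
                 normalize_inputs: bool = True, seed: int = 0):
        if mode not in ("object", "deformation"):
            raise ValueError("mode must be 'object' or 'deformation'")
        self.stimulus_set = stimulus_set
        self.mode = mode
        self.seed = int(seed)
        image_size = stimulus_set.image_shape[0]
        self.gabor_spec = gabor_spec or gb.GaborBankSpec(
            image_size=image_size,
            grid_stride=max(4, image_size // 8),
        )
        self.bank = gb.build_gabor_bank(self.gabor_spec)
        self.layer_configs = layer_configs or nw.default_layer_configs(
            self.bank.layout.grid_shape
        )
        self.learning_params = learning_params or LearningParams(rule=rule)
        if learning_params is None and rule != self.learning_params.rule:
            self.learning_params.rule = rule
        self.normalize_inputs = normalize_inputs
        self._encodings = None

    @classmethod
    def from_stimulus_set(cls, stimulus_set, **kwargs) -> "TraceNetModel":
        return cls(stimulus_set, **kwargs)

    @property
    def encodings(self) -> np.ndarray:
        if self._encodings is None:
            enc = gb.encode_set(self.stimulus_set, self.bank)
            if self.normalize_inputs:
                norms = np.linalg.norm(enc, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                enc = enc / norms
            self._encodings = enc
        return self._encodings

    def schedule(self) -> pr.PresentationSchedule:
        if self.mode == "object":
            return pr.object_mode_schedule(self.stimulus_set, seed=self.seed)
        return pr.deformation_mode_schedule(self.stimulus_set, seed=self.seed)

    def init_network(self) -> nw.Network:
        return nw.init_network(
            self.layer_configs,
            self.bank.layout.grid_shape,
            self.bank.layout.channels_per_position,
            seed=self.seed,
        )

    def fit(self, train: bool = True, log=None) -> "TraceNetResults":
        """Train the hierarchy on this model's schedule (or skip training for
        an untrained-network control with ``train=False``)."""
        network = self.init_network()
        if train:
            train_network(network, self.schedule(), self.learning_params,
                          self.encodings, seed=self.seed + 1, log=log)
        return TraceNetResults(self, network, trained=train)


class TraceNetResults:
    """Trained network plus the measures derived from it."""

    def __init__(self, model: TraceNetModel, network, trained: bool = True):
        self.model = model
        self.network = network
        self.trained = trained
        self._resp = {}

    def responses(self, grouping: str | None = None) -> it.ResponseMatrix:
        """Layer-4 ResponseMatrix; grouping defaults to the trained mode's
        natural class label (identity for object mode, deformation for
        deformation mode)."""
        grouping = grouping or (
            "identity" if self.model.mode == "object" else "deformation"
        )
        if grouping not in self._resp:
            self._resp[grouping] = it.measure_responses(
                self.network,
                self.model.encodings,
                self.model.stimulus_set.labels(),
                grouping=grouping,
            )
        return self._resp[grouping]

    def single_cell_info(self, grouping: str | None = None, n_bins: int = 8):
        resp = self.responses(grouping)
        return it.single_cell_information(resp, n_bins=n_bins)

    def best_cells(self, k: int = 5, grouping: str | None = None,
                   n_bins: int = 8) -> it.SelectedCells:
        resp = self.responses(grouping)
        info, best = self.single_cell_info(grouping, n_bins=n_bins)
        return it.select_best_cells(info, best, k, resp.n_classes)

    def decode(self, k: int = 5, grouping: str | None = None,
               n_bins: int = 8):
        """Multiple-cell information, percent correct and confusion matrix
        from the k best cells per class."""
        resp = self.responses(grouping)
        sel = self.best_cells(k=k, grouping=grouping, n_bins=n_bins)
        return it.multiple_cell_information(resp, sel.cells)

    def population_rates(self) -> np.ndarray:
        """Per-image layer-4 rate vectors (n_images, n_cells)."""
        return population_responses(self.network, self.model.encodings)

    def summary(self, k: int = 5) -> str:
        resp = self.responses()
        info, _ = self.single_cell_info()
        bits, pc, _ = self.decode(k=k)
        s = self.model.stimulus_set
        lines = [
            "Trace-learning hierarchical network results",
            "=" * 47,
            f"stimuli:            {s.kind} ({s.n_id} identities x "
            f"{s.n_def} deformations x {s.n_view} views)",
            f"training mode:      {self.model.mode} "
            f"({'trained' if self.trained else 'untrained control'})",
            f"learning rule:      {self.model.learning_params.rule} "
            f"(eta={self.model.learning_params.trace_eta}, "
            f"alpha={self.model.learning_params.alpha})",
            f"epochs per layer:   {self.model.learning_params.epochs_per_layer}",
            f"stimulus classes:   {resp.n_classes} ({resp.grouping}), "
            f"{resp.n_transforms} transforms each",
            f"info ceiling:       {np.log2(resp.n_classes):.2f} bits",
            f"max single-cell:    {info.max():.2f} bits",
            f"multiple-cell:      {bits:.2f} bits ({k} best cells/class)",
            f"percent correct:    {pc:.1f}%",
        ]
        return "\n".join(lines)
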