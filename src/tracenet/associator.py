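"""One-layer pattern associator used as a readout of selected cells.

Each class accumulates the sum of its training rate vectors (associative
learning), normalized to unit length; classification is the argmax of dot
products, so decisions are invariant to positive scaling of the response.
A delta-rule (error-correcting) training option is available but off by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["AssociatorWeights", "train_associator", "classify", "classify_batch"]


@dataclass
class AssociatorWeights:
    weights: np.ndarray  # (n_classes, n_inputs), unit rows where possible
    classes: list

    def to_json(self) -> str:
        return json.dumps({"classes": list(self.classes),
                           "weights": self.weights.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "AssociatorWeights":
        d = json.loads(payload)
        return cls(weights=np.asarray(d["weights"], dtype=float),
                   classes=d["classes"])


def train_associator(responses: np.ndarray, labels, rule: str = "hebb",
                     lr: float = 0.1, epochs: int = 20) -> AssociatorWeights:
    """Train class weight vectors on (n_examples, n_inputs) responses.

    ``rule='hebb'`` (default): class vector = unit-normalized sum of its
    training vectors. ``rule='delta'``: iterative error-correcting updates on
    one-hot targets, then the same normalization.
    """
    responses = np.asarray(responses, dtype=np.float64)
    labels = list(labels)
    if len(labels) != len(responses):
        raise ValueError("labels and responses must align")
    classes = sorted(set(labels))
    index = {c: i for i, c in enumerate(classes)}
    n_classes, n_inputs = len(classes), responses.shape[1]
    counts = np.bincount([index[l] for l in labels], minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError("every class needs at least one training example")

    if rule == "hebb":
        w = np.zeros((n_classes, n_inputs))
        for r, l in zip(responses, labels):
            w[index[l]] += r
    elif rule == "delta":
        w = np.zeros((n_classes, n_inputs))
        for _ in range(epochs):
            for r, l in zip(responses, labels):
                target = np.zeros(n_classes)
                target[index[l]] = 1.0
                w += lr * np.outer(target - w @ r, r)
    else:
        raise ValueError("rule must be 'hebb' or 'delta'")

    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return AssociatorWeights(weights=w / norms, classes=classes)


def classify(weights: AssociatorWeights, response: np.ndarray):
    """Argmax of class dot products; exact ties (including an all-zero
    response) resolve to the lowest class index."""
    response = np.asarray(response, dtype=np.float64)
    if response.shape != (weights.weights.shape[1],):
        raise ValueError("response dimensionality mismatch")
    scores = weights.weights @ response
    return weights.classes[int(np.argmax(scores))]


def classify_batch(weights: AssociatorWeights, responses: np.ndarray) -> list:
    return [classify(weights, r) for r in np.asarray(responses, dtype=float)]
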