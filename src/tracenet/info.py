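"""Information-theoretic performance measures for the top layer.

Single-cell stimulus-specific information quantifies how much a neuron's
quantized firing rate tells about its most effective stimulus class,

    I(s, R) = sum_r P(r|s) log2( P(r|s) / P(r) ),   reported as max over s,

with the response distributions taken across all transforms (views,
identities or deformations, whichever are not the class label). Multiple-cell
information is estimated by cross-validated population decoding: each
held-out transform is assigned to the class with the nearest mean training
vector (highest normalized dot product) and the mutual information of the
resulting confusion matrix is reported together with percent correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .network import forward_pass

__all__ = [
    "ResponseMatrix",
    "measure_responses",
    "single_cell_information",
    "select_best_cells",
    "SelectedCells",
    "multiple_cell_information",
    "confusion_matrix_information",
    "binomial_exact_test",
]


@dataclass
class ResponseMatrix:
    """Layer rates arranged as cells x stimulus-class x transform.

    ``grouping`` names the label field that defines the stimulus class
    ('identity' or 'deformation'); the remaining label fields enumerate the
    transforms.
    """

    rates: np.ndarray  # (n_cells, n_classes, n_transforms), values in [0, 1]
    grouping: str
    class_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.rates.ndim != 3:
            raise ValueError("rates must be (cells, classes, transforms)")
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("rates must lie in [0, 1]")
        if not self.class_ids:
            self.class_ids = list(range(self.rates.shape[1]))

    @property
    def n_cells(self):
        return self.rates.shape[0]

    @property
    def n_classes(self):
        return self.rates.shape[1]

    @property
    def n_transforms(self):
        return self.rates.shape[2]

    def regroup(self, grouping: str, labels) -> "ResponseMatrix":
        raise NotImplementedError  # regrouping is done in measure_responses

    def to_csv(self, path) -> None:
        """Long format: cell,class,transform,rate."""
        n_c, n_s, n_t = self.rates.shape
        cells, classes, transforms = np.meshgrid(
            np.arange(n_c), np.arange(n_s), np.arange(n_t), indexing="ij"
        )
        pd.DataFrame(
            {
                "cell": cells.ravel(),
                "class": classes.ravel(),
                "transform": transforms.ravel(),
                "rate": self.rates.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grouping: str = "identity") -> "ResponseMatrix":
        df = pd.read_csv(path)
        n_c = df["cell"].max() + 1
        n_s = df["class"].max() + 1
        n_t = df["transform"].max() + 1
        rates = np.zeros((n_c, n_s, n_t))
        rates[df["cell"], df["class"], df["transform"]] = df["rate"]
        return cls(rates=rates, grouping=grouping)


def measure_responses(network, encodings: np.ndarray, labels,
                      grouping: str = "identity",
                      layer: int = 4) -> ResponseMatrix:
    """One forward pass per image; top-layer rates arranged by class and
    transform. No learning side effects.

    ``grouping='identity'`` makes the identity the stimulus class with
    (deformation, view) as transforms; ``grouping='deformation'`` makes the
    deformation the class with (identity, view) as transforms. The two are
    transposed arrangements of the same measured rates.
    """
    if grouping not in ("identity", "deformation"):
        raise ValueError("grouping must be 'identity' or 'deformation'")
    labels = list(labels)
    if len(labels) != len(encodings):
        raise ValueError("labels and encodings must align")
    ids = sorted({l.identity_id for l in labels})
    defs = sorted({l.deformation_id for l in labels})
    views = sorted({l.view_id for l in labels})
    if len(labels) != len(ids) * len(defs) * len(views):
        raise ValueError("stimulus set is not factorially complete")

    n_cells = network.layers[layer - 1].config.n_neurons
    if grouping == "identity":
        n_classes, class_ids = len(ids), ids
        n_transforms = len(defs) * len(views)
    else:
        n_classes, class_ids = len(defs), defs
        n_transforms = len(ids) * len(views)
    rates = np.zeros((n_cells, n_classes, n_transforms))
    id_pos = {v: i for i, v in enumerate(ids)}
    def_pos = {v: i for i, v in enumerate(defs)}
    view_pos = {v: i for i, v in enumerate(views)}
    for enc, lab in zip(encodings, labels):
        y = forward_pass(network, enc, up_to_layer=layer)[-1]
        if grouping == "identity":
            s = id_pos[lab.identity_id]
            t = def_pos[lab.deformation_id] * len(views) + view_pos[lab.view_id]
        else:
            s = def_pos[lab.deformation_id]
            t = id_pos[lab.identity_id] * len(views) + view_pos[lab.view_id]
        rates[:, s, t] = y
    return ResponseMatrix(rates=rates, grouping=grouping, class_ids=class_ids)


def single_cell_information(resp: ResponseMatrix, n_bins: int = 8):
    """Stimulus-specific information of each cell, in bits.

    Each cell's rates are quantized into ``n_bins`` equal-width bins over its
    own observed range; classes have equal priors and the response
    distribution per class is taken across transforms. Returns
    (info_per_cell, best_class_per_cell); a constant-rate cell carries 0 bits.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rates = resp.rates
    n_cells, n_classes, n_transforms = rates.shape
    info = np.zeros(n_cells)
    best = np.zeros(n_cells, dtype=int)
    for c in range(n_cells):
        r = rates[c]
        lo, hi = r.min(), r.max()
        if hi - lo < 1e-15:
            continue
        bins = np.minimum(((r - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        # P(r|s): histogram over transforms per class
        p_r_s = np.zeros((n_classes, n_bins))
        for s in range(n_classes):
            p_r_s[s] = np.bincount(bins[s], minlength=n_bins) / n_transforms
        p_r = p_r_s.mean(axis=0)  # equal class priors
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_r_s > 0, p_r_s / p_r, 1.0)
            i_s = np.sum(np.where(p_r_s > 0, p_r_s * np.log2(ratio), 0.0), axis=1)
        best[c] = int(np.argmax(i_s))
        info[c] = i_s[best[c]]
    return info, best


@dataclass
class SelectedCells:
    per_class: dict  # class index -> list of cell indices (info-ranked)
    shortfall: dict  # class index -> number of cells missing vs k

    @property
    def cells(self) -> list:
        out, seen = [], set()
        for c in sorted(self.per_class):
            for cell in self.per_class[c]:
                if cell not in seen:
                    seen.add(cell)
                    out.append(cell)
        return out


def select_best_cells(info: np.ndarray, best_class: np.ndarray, k: int,
                      n_classes: int) -> SelectedCells:
    """For each class, the k highest-information cells whose most effective
    stimulus is that class; ties broken by lower cell index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    per_class, shortfall = {}, {}
    for s in range(n_classes):
        candidates = np.flatnonzero(best_class == s)
        order = candidates[np.lexsort((candidates, -info[candidates]))]
        chosen = order[:k].tolist()
        per_class[s] = chosen
        shortfall[s] = max(0, k - len(chosen))
    return SelectedCells(per_class=per_class, shortfall=shortfall)


def confusion_matrix_information(confusion: np.ndarray) -> float:
    """Mutual information (bits) of a (actual, decoded) count matrix by
    direct summation."""
    conf = np.asarray(confusion, dtype=np.float64)
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p = conf / total
    ps = p.sum(axis=1, keepdims=True)
    pd_ = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (ps * pd_)), 0.0)
    return float(terms.sum())


def _decode_loto(pop: np.ndarray):
    """Leave-one-transform-out nearest-mean decoding.

    ``pop``: (n_cells, n_classes, n_transforms). Returns the confusion count
    matrix (actual x decoded).
    """
    n_cells, n_classes, n_transforms = pop.shape
    if n_transforms < 2:
        raise ValueError("need at least two transforms per class to cross-validate")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    total = pop.sum(axis=2)  # (cells, classes)
    for t in range(n_transforms):
        means = (total - pop[:, :, t]) / (n_transforms - 1)  # (cells, classes)
        mnorm = np.linalg.norm(means, axis=0)
        mnorm[mnorm == 0] = 1.0
        unit_means = means / mnorm
        for s in range(n_classes):
            v = pop[:, s, t]
            vn = np.linalg.norm(v)
            sims = unit_means.T @ (v / vn if vn > 0 else v)
            decoded = int(np.argmax(sims))  # argmax ties -> lowest index
            confusion[s, decoded] += 1
    return confusion


def multiple_cell_information(resp: ResponseMatrix, cells):
    """Population information and percent correct from cross-validated
    decoding of the selected cells.

    Returns (bits, percent_correct, confusion_matrix).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("need at least one cell")
    pop = resp.rates[cells]
    confusion = _decode_loto(pop)
    pc = 100.0 * np.trace(confusion) / confusion.sum()
    return confusion_matrix_information(confusion), pc, confusion


def binomial_exact_test(k_correct: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k) under chance p0."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k_correct <= n:
        raise ValueError("k_correct must lie in [0, n]")
    return float(binomtest(k_correct, n, p0, alternative="greater").pvalue)
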