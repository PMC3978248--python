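"""Presentation schedules and experimental splits.

The temporal grouping of identical training images is the experimental
manipulation: object mode groups all transforms of one identity so the trace
rule binds them into identity-invariant representations; deformation mode
groups all identities and views sharing one deformation (pose or windspeed)
so deformation-specific, identity-invariant representations form instead.
The image multiset presented per epoch is identical in the two modes — only
the order differs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PresentationSchedule",
    "object_mode_schedule",
    "deformation_mode_schedule",
    "capacity_subsets",
    "leave_one_identity_out_splits",
]


@dataclass
class PresentationSchedule:
    """Ordered groups of stimulus indices with trace-reset boundaries.

    Group order is fixed across epochs; only the order of images within each
    group is re-permuted every epoch (by the training loop).
    """

    groups: list
    mode: str
    seed: int = 0

    def __post_init__(self):
        flat = [i for g in self.groups for i in g]
        if len(set(flat)) != len(flat):
            raise ValueError("schedule groups must partition the stimuli")

    def indices(self) -> list:
        return sorted(i for g in self.groups for i in g)

    def to_json(self) -> str:
        return json.dumps(
            {"mode": self.mode, "seed": self.seed,
             "groups": [list(map(int, g)) for g in self.groups]}
        )

    @classmethod
    def from_json(cls, payload: str) -> "PresentationSchedule":
        d = json.loads(payload)
        return cls(groups=d["groups"], mode=d["mode"], seed=d.get("seed", 0))


def _grouped_schedule(stimulus_set, key, mode, seed):
    labels = stimulus_set.labels()
    n_groups = stimulus_set.n_id if key == "identity_id" else stimulus_set.n_def
    groups = [[] for _ in range(n_groups)]
    order = sorted(
        range(len(labels)),
        key=lambda i: (labels[i].identity_id, labels[i].deformation_id,
                       labels[i].view_id),
    )
    for i in order:
        groups[getattr(labels[i], key)].append(i)
    return PresentationSchedule(groups=groups, mode=mode, seed=seed)


def object_mode_schedule(stimulus_set, seed: int = 0) -> PresentationSchedule:
    """One group per identity, containing all its deformation x view images."""
    return _grouped_schedule(stimulus_set, "identity_id", "object", seed)


def deformation_mode_schedule(stimulus_set, seed: int = 0) -> PresentationSchedule:
    """One group per deformation, containing all identity x view images."""
    return _grouped_schedule(stimulus_set, "deformation_id", "deformation", seed)


def capacity_subsets(object_ids, subset_size: int, n_trials: int,
                     seed: int = 0) -> list:
    """Random object subsets for the capacity experiment, one per trial.

    Each subset is drawn uniformly without replacement from the pool;
    reproducible from the seed.
    """
    object_ids = list(object_ids)
    if subset_size > len(object_ids):
        raise ValueError("subset_size exceeds the object pool")
    rng = np.random.default_rng(seed)
    return [sorted(rng.choice(object_ids, size=subset_size, replace=False).tolist())
            for _ in range(n_trials)]


def leave_one_identity_out_splits(stimulus_set) -> list:
    """(train identities, test identity) pairs, one per identity, in
    identity order."""
    if stimulus_set.n_id < 2:
        raise ValueError("need at least two identities for cross-validation")
    ids = list(range(stimulus_set.n_id))
    return [([i for i in ids if i != test], test) for test in ids]
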