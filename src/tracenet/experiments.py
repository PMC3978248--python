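"""End-to-end experiments: invariance, capacity and cross-validation runs.

Each experiment takes an :class:`ExperimentConfig`, runs stimulus generation,
encoding, training and analysis with explicit seeds, and returns a plain dict
(JSON-serializable) embedding the config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import gabor as gb
from . import info as it
from . import network as nw
from . import protocols as pr
from .associator import train_associator, classify
from .learning import LearningParams
from .model import TraceNetModel
from .stimuli import generate_figure_set, generate_flag_set

__all__ = [
    "ExperimentConfig",
    "run_invariance_experiment",
    "run_capacity_experiment",
    "run_crossval_experiment",
    "image_multiset_hash",
]

DEFAULT_WINDS = (0.0, 50.0, 100.0, 150.0, 200.0)


@dataclass
class ExperimentConfig:
    """Configuration for one experiment run; round-trips through YAML."""

    stimulus_kind: str = "figure"  # 'figure' or 'flag'
    n_identities: int = 3
    n_views: int = 12  # figures; flags always use the two mirrored views
    wind_levels: tuple = DEFAULT_WINDS
    poses: tuple = ("sitting", "standing", "walking")
    image_size: int = 64
    stimulus_seed: int = 1

    mode: str = "object"
    rule: str = "trace"
    alpha: float = 0.3
    trace_eta: float = 0.8
    epochs_per_layer: int = 50
    network_seed: int = 0

    grid: int = 24
    fan_in: int = 100
    sparseness_percentile: float = 10.0
    sigmoid_slope: float = 30.0

    n_bins: int = 8
    k_best: int = 5

    # capacity experiment
    subset_sizes: tuple = (4, 8, 10, 15, 20)
    n_trials: int = 20
    flag_pool: int = 28

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- builders -----------------------------------------------------------

    def make_stimuli(self, n_identities=None, seed=None):
        n_id = n_identities if n_identities is not None else self.n_identities
        seed = self.stimulus_seed if seed is None else seed
        if self.stimulus_kind == "flag":
            return generate_flag_set(
                n_id, wind_levels=self.wind_levels, image_size=self.image_size,
                seed=seed,
            )
        if self.stimulus_kind == "figure":
            return generate_figure_set(
                n_id, poses=self.poses, n_views=self.n_views,
                image_size=self.image_size, seed=seed,
            )
        raise ValueError("stimulus_kind must be 'flag' or 'figure'")

    def make_model(self, stimulus_set, mode=None, rule=None, epochs=None,
                   seed=None) -> TraceNetModel:
        params = LearningParams(
            rule=rule or self.rule,
            alpha=self.alpha,
            trace_eta=self.trace_eta,
            epochs_per_layer=self.epochs_per_layer if epochs is None else epochs,
        )
        image_size = stimulus_set.image_shape[0]
        spec = gb.GaborBankSpec(
            image_size=image_size,
            grid_stride=max(4, image_size // 8),
        )
        bank = gb.build_gabor_bank(spec)
        configs = [
            dataclasses.replace(
                c,
                sparseness_percentile=self.sparseness_percentile,
                sigmoid_slope=self.sigmoid_slope,
            )
            for c in nw.default_layer_configs(
                bank.layout.grid_shape, grid=self.grid, fan_in=self.fan_in
            )
        ]
        return TraceNetModel(
            stimulus_set,
            mode=mode or self.mode,
            gabor_spec=spec,
            layer_configs=configs,
            learning_params=params,
            seed=self.network_seed if seed is None else seed,
        )


def image_multiset_hash(stimulus_set) -> str:
    """Hash of the sorted image byte strings: identifies the image multiset
    irrespective of presentation order."""
    digests = sorted(
        hashlib.sha256(im.tobytes()).hexdigest() for im, _ in stimulus_set.items
    )
    return hashlib.sha256("".join(digests).encode()).hexdigest()[:16]


def run_invariance_experiment(config: ExperimentConfig) -> dict:
    """Train in the configured mode/rule and measure identity or deformation
    decoding across the remaining transforms."""
    if config.mode not in ("object", "deformation"):
        raise ValueError("mode must be 'object' or 'deformation'")
    if config.rule not in ("trace", "hebb"):
        raise ValueError("rule must be 'trace' or 'hebb'")
    stimulus_set = config.make_stimuli()
    model = config.make_model(stimulus_set)
    results = model.fit()
    info, best = results.single_cell_info(n_bins=config.n_bins)
    resp = results.responses()
    bits, pc, confusion = results.decode(k=config.k_best, n_bins=config.n_bins)
    return {
        "experiment": "invariance",
        "config_hash": config.config_hash(),
        "seeds": {"stimulus": config.stimulus_seed, "network": config.network_seed},
        "mode": config.mode,
        "rule": config.rule,
        "grouping": resp.grouping,
        "n_classes": resp.n_classes,
        "image_multiset_hash": image_multiset_hash(stimulus_set),
        "info_ceiling_bits": float(np.log2(resp.n_classes)),
        "max_single_cell_bits": float(info.max()),
        "multiple_cell_bits": float(bits),
        "percent_correct": float(pc),
        "confusion": confusion.tolist(),
    }


def run_capacity_experiment(config: ExperimentConfig) -> dict:
    """Random-subset capacity runs over increasing numbers of flags.

    For each subset size, ``n_trials`` independent networks are trained in
    object mode on a random subset of the flag pool and country decoding
    accuracy is recorded; reports mean and sd percent correct per size.
    """
    cfg = dataclasses.replace(config, stimulus_kind="flag", mode="object")
    pool_set = cfg.make_stimuli(n_identities=cfg.flag_pool)
    # encode the full pool once; each trial reuses the rows of its subset
    probe_model = cfg.make_model(pool_set)
    pool_encodings = probe_model.encodings

    rng_seed = cfg.network_seed
    curve = []
    for size in cfg.subset_sizes:
        if size > cfg.flag_pool:
            raise ValueError("subset size exceeds flag pool")
        subsets = pr.capacity_subsets(
            range(cfg.flag_pool), size, cfg.n_trials, seed=rng_seed + size
        )
        pcs = []
        for trial, subset in enumerate(subsets):
            idx = [
                i
                for i, (_, l) in enumerate(pool_set.items)
                if l.identity_id in set(subset)
            ]
            sub_set = pool_set.subset_identities(subset)
            model = cfg.make_model(
                sub_set, mode="object", seed=rng_seed + 1000 * size + trial
            )
            model._encodings = pool_encodings[idx]
            results = model.fit()
            _, pc, _ = results.decode(k=cfg.k_best, n_bins=cfg.n_bins)
            pcs.append(pc)
        pcs = np.asarray(pcs)
        curve.append(
            {
                "subset_size": int(size),
                "n_trials": int(cfg.n_trials),
                "mean_percent_correct": float(pcs.mean()),
                "sd_percent_correct": float(pcs.std(ddof=1)) if len(pcs) > 1 else 0.0,
                "trials": pcs.tolist(),
            }
        )
    return {
        "experiment": "capacity",
        "config_hash": cfg.config_hash(),
        "seeds": {"stimulus": cfg.stimulus_seed, "network": cfg.network_seed},
        "epochs_per_layer": cfg.epochs_per_layer,
        "curve": curve,
    }


def _crossval_one_split(cfg, full_set, encodings, train_ids, test_id, train):
    """One leave-one-identity-out split; returns per-image hits on the
    held-out identity."""
    train_idx = [
        i for i, (_, l) in enumerate(full_set.items) if l.identity_id in set(train_ids)
    ]
    test_idx = [
        i for i, (_, l) in enumerate(full_set.items) if l.identity_id == test_id
    ]
    train_set = full_set.subset_identities(train_ids)
    model = cfg.make_model(
        train_set, mode="deformation", seed=cfg.network_seed + 100 + test_id
    )
    model._encodings = encodings[train_idx]
    results = model.fit(train=train)

    info, best = results.single_cell_info(n_bins=cfg.n_bins)
    resp = results.responses("deformation")
    sel = it.select_best_cells(info, best, cfg.k_best, resp.n_classes)
    cells = sel.cells

    train_rates = results.population_rates()[:, cells]
    train_labels = [l.deformation_id for _, l in train_set.items]
    weights = train_associator(train_rates, train_labels)

    from .model import population_responses

    test_rates = population_responses(results.network, encodings[test_idx])[:, cells]
    test_labels = [full_set.items[i][1].deformation_id for i in test_idx]
    hits = [
        int(classify(weights, r) == lab) for r, lab in zip(test_rates, test_labels)
    ]
    return hits, len(cells)


def run_crossval_experiment(config: ExperimentConfig) -> dict:
    """Leave-one-identity-out pose generalization with a pattern-associator
    readout of the selected cells, plus the untrained-network control."""
    cfg = dataclasses.replace(config, stimulus_kind="figure", mode="deformation")
    full_set = cfg.make_stimuli()
    if full_set.n_id < 2:
        raise ValueError("cross-validation needs at least two identities")
    probe = cfg.make_model(full_set)
    encodings = probe.encodings
    splits = pr.leave_one_identity_out_splits(full_set)

    def run_all(train):
        per_identity = []
        all_hits = []
        for train_ids, test_id in splits:
            hits, n_cells = _crossval_one_split(
                cfg, full_set, encodings, train_ids, test_id, train
            )
            per_identity.append(
                {
                    "test_identity": int(test_id),
                    "accuracy_percent": 100.0 * np.mean(hits),
                    "n_test": len(hits),
                    "n_readout_cells": int(n_cells),
                }
            )
            all_hits.extend(hits)
        return per_identity, all_hits

    per_identity, hits = run_all(train=True)
    chance = 1.0 / full_set.n_def
    k_correct = int(np.sum(hits))
    accs = np.array([p["accuracy_percent"] for p in per_identity])
    control_per_identity, control_hits = run_all(train=False)
    return {
        "experiment": "crossval",
        "config_hash": cfg.config_hash(),
        "seeds": {"stimulus": cfg.stimulus_seed, "network": cfg.network_seed},
        "n_identities": full_set.n_id,
        "chance_percent": 100.0 * chance,
        "overall_accuracy_percent": 100.0 * k_correct / len(hits),
        "per_identity": per_identity,
        "per_identity_sd_percent": float(accs.std(ddof=1)),
        "binomial_p_value": it.binomial_exact_test(k_correct, len(hits), chance),
        "untrained_accuracy_percent": 100.0 * np.mean(control_hits),
        "untrained_per_identity": control_per_identity,
    }
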