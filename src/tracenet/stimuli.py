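"""Synthetic factorial stimulus sets: deforming flags and articulated figures.

The corpora emulate the statistical structure of rendered training sets used
for invariance experiments: grayscale images on a uniform gray-127 background,
organised factorially as identity x deformation x view, where

* the identity cue (stripe/emblem pattern for flags, limb proportions and
  body tones for figures) is constant across deformation and view,
* the deformation cue (wind droop for flags, pose template for figures) is
  constant across identities, and
* views are parametric rotations/mirrors.

Images are drawn anti-aliased at 2x supersampling, mean-pooled and quantized
to 8-bit. Every background pixel is exactly 127.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

BACKGROUND = 127
_SUPERSAMPLE = 2

__all__ = [
    "StimulusLabel",
    "StimulusSet",
    "generate_flag_set",
    "generate_figure_set",
    "figure_identity_params",
    "save_set",
    "load_set",
    "FLAG_PATTERN_LIBRARY_SIZE",
]


@dataclass(frozen=True)
class StimulusLabel:
    """Factorial coordinates of one stimulus image.

    ``deformation_level`` is the physical deformation parameter: wind force in
    [0, 200] for flags, the pose name for figures.
    """

    identity_id: int
    deformation_id: int
    view_id: int
    view_angle: float
    deformation_level: object


@dataclass
class StimulusSet:
    """A complete factorial collection of labeled grayscale images."""

    items: list  # list of (np.ndarray uint8, StimulusLabel)
    n_id: int
    n_def: int
    n_view: int
    seed: int
    kind: str = "generic"
    identity_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.items) != self.n_id * self.n_def * self.n_view:
            raise ValueError(
                f"expected {self.n_id * self.n_def * self.n_view} items, "
                f"got {len(self.items)}"
            )
        triples = {(l.identity_id, l.deformation_id, l.view_id) for _, l in self.items}
        if len(triples) != len(self.items):
            raise ValueError("duplicate (identity, deformation, view) label triple")
        shapes = {im.shape for im, _ in self.items}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image dimensions: {shapes}")

    @property
    def image_shape(self):
        return self.items[0][0].shape

    def images(self) -> np.ndarray:
        """All images stacked (n_items, h, w), in item order."""
        return np.stack([im for im, _ in self.items])

    def labels(self) -> list:
        return [l for _, l in self.items]

    def index_of(self, identity_id: int, deformation_id: int, view_id: int) -> int:
        for i, (_, l) in enumerate(self.items):
            if (l.identity_id, l.deformation_id, l.view_id) == (
                identity_id,
                deformation_id,
                view_id,
            ):
                return i
        raise KeyError((identity_id, deformation_id, view_id))

    def subset_identities(self, identity_ids) -> "StimulusSet":
        """Restrict to the given identities, re-indexing identity_id densely."""
        identity_ids = list(identity_ids)
        remap = {old: new for new, old in enumerate(identity_ids)}
        items = []
        for im, l in self.items:
            if l.identity_id in remap:
                items.append(
                    (
                        im,
                        StimulusLabel(
                            remap[l.identity_id],
                            l.deformation_id,
                            l.view_id,
                            l.view_angle,
                            l.deformation_level,
                        ),
                    )
                )
        params = {
            remap[i]: p for i, p in self.identity_params.items() if i in remap
        }
        return StimulusSet(
            items=items,
            n_id=len(identity_ids),
            n_def=self.n_def,
            n_view=self.n_view,
            seed=self.seed,
            kind=self.kind,
            identity_params=params,
        )


# ---------------------------------------------------------------------------
# flag patterns
# ---------------------------------------------------------------------------

def _flag_pattern_descriptors():
    """Procedural library of distinct stripe/cross/canton layouts.

    No real national flag artwork is reproduced; the library only provides 28
    mutually distinct pixel patterns whose layout is a pure function of the
    country index.
    """
    descs = []
    for n in (2, 3, 4, 5):
        descs.append(("hstripes", n))
    for n in (2, 3, 4, 5):
        descs.append(("vstripes", n))
    for n in (2, 3, 4, 5):
        descs.append(("checker", n))
    for t in (0.08, 0.14, 0.20):
        descs.append(("cross", t))
    for t in (0.10, 0.18):
        descs.append(("border", t))
    for n in (2, 3, 4):
        descs.append(("canton_h", n))
    for n in (2, 3, 4):
        descs.append(("canton_v", n))
    descs.append(("diag", 1))
    descs.append(("diag", -1))
    for t in (0.10, 0.18):
        descs.append(("disc", 0.22 + t))
    descs.append(("tristripe_disc", 0.18))
    return descs  # 28 entries


_FLAG_DESCRIPTORS = _flag_pattern_descriptors()
FLAG_PATTERN_LIBRARY_SIZE = len(_FLAG_DESCRIPTORS)

_TONE_POOL = np.array([0.0, 45.0, 85.0, 170.0, 210.0, 255.0])


def _flag_tones(idx: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 104729, idx])
    return rng.choice(_TONE_POOL, size=3, replace=False)


def _pattern_values(desc, tones, u, v):
    """Gray value of the flag pattern at normalised cloth coordinates."""
    kind, p = desc
    out = np.empty_like(u)
    if kind == "hstripes":
        band = np.minimum((v * p).astype(int), p - 1)
        out = tones[band % len(tones)]
    elif kind == "vstripes":
        band = np.minimum((u * p).astype(int), p - 1)
        out = tones[band % len(tones)]
    elif kind == "checker":
        bu = np.minimum((u * p).astype(int), p - 1)
        bv = np.minimum((v * p).astype(int), p - 1)
        out = np.where((bu + bv) % 2 == 0, tones[0], tones[1])
    elif kind == "cross":
        on = (np.abs(u - 0.5) < p) | (np.abs(v - 0.5) < p)
        out = np.where(on, tones[1], tones[0])
    elif kind == "border":
        on = (u < p) | (u > 1 - p) | (v < p) | (v > 1 - p)
        out = np.where(on, tones[1], tones[0])
    elif kind in ("canton_h", "canton_v"):
        n = p
        if kind == "canton_h":
            band = np.minimum((v * n).astype(int), n - 1)
        else:
            band = np.minimum((u * n).astype(int), n - 1)
        out = np.where(band % 2 == 0, tones[0], tones[1])
        out = np.where((u < 0.42) & (v < 0.46), tones[2], out)
    elif kind == "diag":
        if p > 0:
            on = u + v < 1.0
        else:
            on = u > v
        out = np.where(on, tones[0], tones[1])
    elif kind == "disc":
        r2 = (u - 0.5) ** 2 + (v - 0.5) ** 2
        out = np.where(r2 < p**2, tones[1], tones[0])
    elif kind == "tristripe_disc":
        band = np.minimum((v * 3).astype(int), 2)
        out = tones[band % len(tones)]
        r2 = (u - 0.5) ** 2 + (v - 0.5) ** 2
        out = np.where(r2 < p**2, tones[2], out)
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern kind {kind!r}")
    return out


def _render_flag(desc, tones, wind: float, image_size: int) -> np.ndarray:
    """Draw one flag at the given wind force, front (0 degree) view.

    Deformation is a column-wise vertical droop proportional to
    (wind/200) * u^2 (u = normalised distance from the hoist) plus a
    low-amplitude sinusoidal ripple that also vanishes at the hoist; the
    displacement field depends on wind only, never on the pattern.
    """
    ss = _SUPERSAMPLE
    n = image_size * ss
    fw = int(round(0.64 * image_size)) * ss
    fh = int(round(0.34 * image_size)) * ss
    x0 = (n - fw) // 2
    y0 = int(round(0.10 * image_size)) * ss

    # strong wind (0 deformation) = cloth blown straight out; zero wind
    # (max deformation) = fly end hanging well below the hoist, so the
    # silhouette sweeps a range comparable to a real languid-to-blown-out flag
    droop_max = 0.45 * n
    ripple_amp = 0.035 * n

    xs = np.arange(n, dtype=float)
    ys = np.arange(n, dtype=float)
    X, Y = np.meshgrid(xs, ys)

    u = (X - x0) / fw
    w = wind / 200.0
    with np.errstate(invalid="ignore"):
        shift = (w * droop_max * np.abs(u) ** 1.5
                 + w * ripple_amp * np.sin(3 * np.pi * u) * u)
    v = (Y - y0 - shift) / fh

    inside = (u >= 0) & (u < 1) & (v >= 0) & (v < 1)
    canvas = np.full((n, n), float(BACKGROUND))
    uu = np.clip(u, 0, 1 - 1e-9)
    vv = np.clip(v, 0, 1 - 1e-9)
    vals = _pattern_values(desc, tones, uu, vv)
    canvas[inside] = vals[inside]

    pooled = canvas.reshape(image_size, ss, image_size, ss).mean(axis=(1, 3))
    return np.clip(np.rint(pooled), 0, 255).astype(np.uint8)


def generate_flag_set(
    n_countries: int,
    wind_levels=(0.0, 50.0, 100.0, 150.0, 200.0),
    views=(0.0, 180.0),
    image_size: int = 128,
    seed: int = 0,
) -> StimulusSet:
    """Generate a factorial flag corpus: country x wind deformation x view.

    Each country index maps deterministically to a distinct pattern from the
    procedural library; at equal wind the droop displacement is identical
    across countries; the 180-degree view is the exact horizontal mirror of
    the 0-degree view.
    """
    if not 1 <= n_countries <= FLAG_PATTERN_LIBRARY_SIZE:
        raise ValueError(
            f"n_countries must be in [1, {FLAG_PATTERN_LIBRARY_SIZE}]"
        )
    wind_levels = [float(w) for w in wind_levels]
    if not wind_levels:
        raise ValueError("wind_levels must be non-empty")
    for w in wind_levels:
        if not 0.0 <= w <= 200.0:
            raise ValueError(f"wind level {w} outside [0, 200]")
    views = [float(a) for a in views]
    for a in views:
        if a not in (0.0, 180.0):
            raise ValueError("flag views must be from {0, 180} degrees")
    if image_size < 32:
        raise ValueError("image_size too small to render flag pattern features")

    items = []
    identity_params = {}
    for cid in range(n_countries):
        desc = _FLAG_DESCRIPTORS[cid]
        tones = _flag_tones(cid, seed)
        # center foreground mean on the background gray in the reference
        # (wind 0, front view) condition; the same tone shift applies to all
        # deformations and views of this country
        ref = _render_flag(desc, tones, 0.0, image_size).astype(float)
        fg = ref[ref != BACKGROUND]
        if fg.size:
            tones = np.clip(tones + (BACKGROUND - fg.mean()), 5, 250)
        identity_params[cid] = np.concatenate(([float(cid)], tones))
        for did, wind in enumerate(wind_levels):
            front = _render_flag(desc, tones, wind, image_size)
            for vid, angle in enumerate(views):
                img = front if angle == 0.0 else np.fliplr(front).copy()
                items.append(
                    (
                        img,
                        StimulusLabel(cid, did, vid, angle, wind),
                    )
                )
    return StimulusSet(
        items=items,
        n_id=n_countries,
        n_def=len(wind_levels),
        n_view=len(views),
        seed=seed,
        kind="flag",
        identity_params=identity_params,
    )


# ---------------------------------------------------------------------------
# articulated figures
# ---------------------------------------------------------------------------

POSES = ("sitting", "standing", "walking")

# joint-angle templates, degrees; positive = forward (towards +x before any
# view transform). Identical for every individual: the pose cue is shared.
_POSE_TEMPLATES = {
    "standing": {
        "torso": 0.0,
        "thigh_l": 2.0,
        "thigh_r": -2.0,
        "knee_l": 0.0,
        "knee_r": 0.0,
        "arm_l": 8.0,
        "arm_r": -8.0,
        "elbow_l": 5.0,
        "elbow_r": -5.0,
    },
    "sitting": {
        "torso": -8.0,
        "thigh_l": 85.0,
        "thigh_r": 80.0,
        "knee_l": -88.0,
        "knee_r": -85.0,
        "arm_l": 35.0,
        "arm_r": 30.0,
        "elbow_l": 40.0,
        "elbow_r": 40.0,
    },
    "walking": {
        "torso": 6.0,
        "thigh_l": 32.0,
        "thigh_r": -22.0,
        "knee_l": -15.0,
        "knee_r": -45.0,
        "arm_l": -30.0,
        "arm_r": 35.0,
        "elbow_l": -20.0,
        "elbow_r": 25.0,
    },
}


def figure_identity_params(seed: int, identity_id: int) -> np.ndarray:
    """Deterministic identity parameter vector: limb proportions and tones.

    Bit-identical for a given (seed, identity_id) regardless of pose or view.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7919, identity_id])
    props = rng.uniform(0.82, 1.18, size=8)  # torso, thigh, shin, upper arm,
    # forearm, head radius, shoulder width, limb thickness
    tones = rng.uniform(35.0, 225.0, size=3)  # torso, limbs, head
    # keep tones mutually separated so the texture cue is visible
    tones = np.sort(tones)
    tones[1] = max(tones[1], tones[0] + 40.0)
    tones[2] = max(tones[2], tones[1] + 40.0)
    tones = np.clip(tones, 5.0, 250.0)
    order = rng.permutation(3)
    return np.concatenate([props, tones[order]])


def _figure_segments(params: np.ndarray, pose: str):
    """Capsule segments (p1, p2, radius, tone) in body coordinates.

    Body coordinates: y up, pelvis at origin, unit ~ body height fraction.
    """
    t = _POSE_TEMPLATES[pose]
    (torso_f, thigh_f, shin_f, uarm_f, farm_f, head_f, shw_f, thick_f) = params[:8]
    torso_tone, limb_tone, head_tone = params[8:11]

    torso_len = 0.34 * torso_f
    thigh_len = 0.26 * thigh_f
    shin_len = 0.24 * shin_f
    uarm_len = 0.18 * uarm_f
    farm_len = 0.16 * farm_f
    head_r = 0.075 * head_f
    shoulder_w = 0.10 * shw_f
    thick = 0.040 * thick_f

    # polar step: angle measured from straight down for limbs, from straight
    # up for the torso
    def down(p, angle_deg, length):
        a = np.deg2rad(angle_deg)
        return p + length * np.array([np.sin(a), -np.cos(a)])

    def up(p, angle_deg, length):
        a = np.deg2rad(angle_deg)
        return p + length * np.array([np.sin(a), np.cos(a)])

    pelvis = np.array([0.0, 0.0])
    neck = up(pelvis, t["torso"], torso_len)
    segs = []
    # torso drawn wide
    segs.append((pelvis, neck, 0.09 * shw_f + 0.4 * thick, torso_tone))
    # head
    head_c = up(neck, t["torso"], head_r * 1.6)
    segs.append((head_c, head_c, head_r, head_tone))
    # legs
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        hip = pelvis + np.array([sgn * 0.045, 0.0])
        knee = down(hip, t[f"thigh_{side}"], thigh_len)
        ankle = down(knee, t[f"thigh_{side}"] + t[f"knee_{side}"], shin_len)
        segs.append((hip, knee, thick, limb_tone))
        segs.append((knee, ankle, thick * 0.9, limb_tone))
    # arms
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        sh = neck + np.array([sgn * shoulder_w, -0.02])
        elbow = down(sh, t[f"arm_{side}"], uarm_len)
        wrist = down(elbow, t[f"arm_{side}"] + t[f"elbow_{side}"], farm_len)
        segs.append((sh, elbow, thick * 0.85, limb_tone))
        segs.append((elbow, wrist, thick * 0.75, limb_tone))
    return segs


def _render_figure(params: np.ndarray, pose: str, angle_deg: float,
                   image_size: int) -> np.ndarray:
    """Draw the figure at a view angle.

    True 3-D rotation is approximated parametrically: all horizontal body
    coordinates are scaled by 0.35 + 0.65*|cos(angle)| and the silhouette is
    mirrored on the rear half of the view circle.
    """
    segs = _figure_segments(params, pose)
    a = np.deg2rad(angle_deg)
    # articulated bodies are deep as well as wide, so even a profile view
    # keeps substantial horizontal structure: the modulation floor is high
    # enough that pose stays legible at every view
    width_factor = 0.55 + 0.45 * abs(np.cos(a))
    mirror = -1.0 if np.cos(a) < 0 else 1.0

    ss = _SUPERSAMPLE
    n = image_size * ss
    scale = 0.62 * n  # body height ~ 62% of frame
    cx, cy = n / 2.0, 0.70 * n  # pelvis position (y grows downward)

    ys, xs = np.mgrid[0:n, 0:n]
    canvas = np.full((n, n), float(BACKGROUND))

    for p1, p2, r, tone in segs:
        q1 = np.array([cx + mirror * width_factor * p1[0] * scale,
                       cy - p1[1] * scale])
        q2 = np.array([cx + mirror * width_factor * p2[0] * scale,
                       cy - p2[1] * scale])
        rr = r * scale
        d = q2 - q1
        L2 = d @ d
        px = xs - q1[0]
        py = ys - q1[1]
        if L2 < 1e-12:
            dist2 = px**2 + py**2
        else:
            tpar = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0)
            dist2 = (px - tpar * d[0]) ** 2 + (py - tpar * d[1]) ** 2
        canvas[dist2 <= rr**2] = tone

    pooled = canvas.reshape(image_size, ss, image_size, ss).mean(axis=(1, 3))
    return np.clip(np.rint(pooled), 0, 255).astype(np.uint8)


def generate_figure_set(
    n_individuals: int,
    poses=POSES,
    n_views: int = 12,
    image_size: int = 128,
    seed: int = 0,
) -> StimulusSet:
    """Generate a factorial figure corpus: individual x pose x view.

    Pose fixes a joint-angle template shared by all individuals; identity
    fixes limb proportions and body tones shared across all poses and views;
    view k rotates the camera by k*360/n_views, approximated by silhouette
    width modulation plus mirroring.

    The foreground tones of each individual are shifted once so that the mean
    foreground intensity in the reference condition (standing, view 0, when
    present) equals the background gray; all other conditions inherit the
    same tones unrenormalized.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    poses = list(poses)
    if not poses:
        raise ValueError("poses must be non-empty")
    for p in poses:
        if p not in _POSE_TEMPLATES:
            raise ValueError(f"unknown pose {p!r}; choose from {POSES}")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if image_size < 32:
        raise ValueError("image_size too small to render figure features")

    items = []
    identity_params = {}
    ref_pose = "standing" if "standing" in poses else poses[0]
    for iid in range(n_individuals):
        params = figure_identity_params(seed, iid)
        ref = _render_figure(params, ref_pose, 0.0, image_size).astype(float)
        fg = ref[ref != BACKGROUND]
        if fg.size:
            params = params.copy()
            params[8:11] = np.clip(params[8:11] + (BACKGROUND - fg.mean()), 5, 250)
        identity_params[iid] = params
        for did, pose in enumerate(poses):
            for vid in range(n_views):
                angle = vid * 360.0 / n_views
                img = _render_figure(params, pose, angle, image_size)
                items.append((img, StimulusLabel(iid, did, vid, angle, pose)))
    return StimulusSet(
        items=items,
        n_id=n_individuals,
        n_def=len(poses),
        n_view=n_views,
        seed=seed,
        kind="figure",
        identity_params=identity_params,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
_MANIFEST_COLS = [
    "filename",
    "identity_id",
    "deformation_id",
    "view_id",
    "view_angle_deg",
    "deformation_level",
    "seed",
]


def save_set(stimulus_set: StimulusSet, directory, image_format: str = "png") -> str:
    """Write one lossless grayscale file per item plus a CSV manifest.

    Returns the manifest path. ``image_format`` is ``"png"`` or ``"pgm"``
    (binary P5).
    """
    if image_format not in ("png", "pgm"):
        raise ValueError("image_format must be 'png' or 'pgm'")
    os.makedirs(directory, exist_ok=True)
    rows = []
    for im, l in stimulus_set.items:
        fname = (
            f"{stimulus_set.kind}_i{l.identity_id:03d}_d{l.deformation_id:03d}"
            f"_v{l.view_id:03d}.{image_format}"
        )
        Image.fromarray(im, mode="L").save(os.path.join(directory, fname))
        rows.append(
            {
                "filename": fname,
                "identity_id": l.identity_id,
                "deformation_id": l.deformation_id,
                "view_id": l.view_id,
                "view_angle_deg": l.view_angle,
                "deformation_level": l.deformation_level,
                "seed": stimulus_set.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    path = os.path.join(directory, MANIFEST_NAME)
    manifest.to_csv(path, index=False)
    return path


def load_set(directory, kind: str = "generic") -> StimulusSet:
    """Reconstruct a StimulusSet from a directory written by :func:`save_set`."""
    path = os.path.join(directory, MANIFEST_NAME)
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    triples = list(
        zip(manifest.identity_id, manifest.deformation_id, manifest.view_id)
    )
    if len(set(triples)) != len(triples):
        raise ValueError("manifest contains duplicate label triples")
    items = []
    for row in manifest.itertuples(index=False):
        fpath = os.path.join(directory, row.filename)
        if not os.path.exists(fpath):
            raise ValueError(f"manifest lists missing image file: {row.filename}")
        with Image.open(fpath) as handle:
            im = np.asarray(handle.convert("L"), dtype=np.uint8)
        items.append(
            (
                im,
                StimulusLabel(
                    int(row.identity_id),
                    int(row.deformation_id),
                    int(row.view_id),
                    float(row.view_angle_deg),
                    row.deformation_level,
                ),
            )
        )
    kind_guess = kind
    if kind == "generic" and len(manifest):
        stem = str(manifest.filename.iloc[0])
        for k in ("flag", "figure"):
            if stem.startswith(k):
                kind_guess = k
    return StimulusSet(
        items=items,
        n_id=int(manifest.identity_id.max()) + 1,
        n_def=int(manifest.deformation_id.max()) + 1,
        n_view=int(manifest.view_id.max()) + 1,
        seed=int(manifest.seed.iloc[0]) if len(manifest) else 0,
        kind=kind_guess,
    )
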