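"""Three-way-decision classifier via the optimal-center constructive
covering algorithm (O_CCA).

Training min-max normalizes the feature rows, lifts them onto an
(n+1)-dimensional sphere of radius R (appending sqrt(R^2 - |x|^2) so all
points share a common norm), and then greedily covers each class with
Euclidean balls: repeatedly take the still-uncovered points of one
class, pick as center the member nearest their mean, give the cover the
largest radius that excludes every opposite-class training point, and
mark the members it contains as covered. The result is a set of
per-class (center, radius) covers with two structural guarantees: every
training point lies in a cover of its own class, and no training point
lies strictly inside an opposite-class cover.

Prediction is three-way: a point claimed by covers of exactly one class
gets that class (the positive or negative region); a point claimed by
both classes or by neither falls in the boundary region and the
classifier abstains. No probability thresholds or loss functions are
involved — the regions emerge from the cover geometry alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from eeg3wd.entropy import BOUNDARY

_MODEL_FORMAT_VERSION = 1


@dataclass
class Cover:
    """One covering ball on the lifted sphere."""

    center: np.ndarray
    radius: float
    label: int
    member_count: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius < 0:
            raise ValueError("cover radius must be nonnegative")
        if self.member_count < 1:
            raise ValueError("a cover must contain at least one member")
        if self.label not in (0, 1):
            raise ValueError("cover label must be 0 or 1")


@dataclass
class Decision:
    """Outcome of a three-way decision.

    ``region`` is POS (accept class 0), NEG (accept class 1), or BND
    (abstain); ``predicted_label`` is 0, 1, or the boundary token.
    """

    region: str
    predicted_label: int | str

    def __post_init__(self) -> None:
        valid = {"POS": 0, "NEG": 1, "BND": BOUNDARY}
        if self.region not in valid:
            raise ValueError(f"region must be POS/NEG/BND, got {self.region!r}")
        if self.predicted_label != valid[self.region]:
            raise ValueError(
                f"region {self.region} inconsistent with predicted label "
                f"{self.predicted_label!r}"
            )


@dataclass
class CoverModel:
    """Trained cover set plus the normalization and lifting parameters."""

    covers: list[Cover]
    feature_mins: np.ndarray
    feature_ranges: np.ndarray
    R: float
    radius_mode: str = "midpoint"

    def __post_init__(self) -> None:
        self.feature_mins = np.asarray(self.feature_mins, dtype=float)
        self.feature_ranges = np.asarray(self.feature_ranges, dtype=float)

    @property
    def n_features(self) -> int:
        return self.feature_mins.size

    def covers_of(self, label: int) -> list[Cover]:
        return [c for c in self.covers if c.label == label]

    def to_json(self) -> str:
        doc = {
            "format_version": _MODEL_FORMAT_VERSION,
            "radius_mode": self.radius_mode,
            "R": self.R,
            "feature_mins": self.feature_mins.tolist(),
            "feature_ranges": self.feature_ranges.tolist(),
            "covers": [
                {
                    "center": c.center.tolist(),
                    "radius": c.radius,
                    "label": c.label,
                    "member_count": c.member_count,
                }
                for c in self.covers
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CoverModel":
        doc = json.loads(text)
        version = doc.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        return cls(
            covers=[
                Cover(
                    center=np.array(c["center"], dtype=float),
                    radius=float(c["radius"]),
                    label=int(c["label"]),
                    member_count=int(c["member_count"]),
                )
                for c in doc["covers"]
            ],
            feature_mins=np.array(doc["feature_mins"], dtype=float),
            feature_ranges=np.array(doc["feature_ranges"], dtype=float),
            R=float(doc["R"]),
            radius_mode=doc["radius_mode"],
        )


def normalize_fit(train) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-dimension min-max parameters on training rows.

    A zero-range (constant) dimension gets range 1 so it maps to the
    constant 0 instead of dividing by zero.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.size == 0:
        raise ValueError("cannot fit normalization on an empty table")
    mins = train.min(axis=0)
    ranges = train.max(axis=0) - mins
    ranges[ranges == 0] = 1.0
    return mins, ranges


def normalize_apply(x, mins, ranges, clip: bool = False) -> np.ndarray:
    """Apply fitted min-max parameters; optionally clip into [0, 1]."""
    z = (np.asarray(x, dtype=float) - mins) / ranges
    if clip:
        z = np.clip(z, 0.0, 1.0)
    return z


def sphere_project(x, R: float) -> np.ndarray:
    """Lift a normalized n-vector onto the sphere of radius R in n+1 dims.

    Appends sqrt(R^2 - |x|^2) so the lifted point has norm exactly R;
    requires |x| <= R.
    """
    x = np.asarray(x, dtype=float)
    sq = R * R - float(x @ x)
    if sq < -1e-9 * R * R:
        raise ValueError(
            f"|x| = {np.linalg.norm(x):.6g} exceeds lifting radius R = {R:.6g}"
        )
    return np.append(x, np.sqrt(max(sq, 0.0)))


def cover_radius(center, same, enemy, mode: str = "midpoint") -> float:
    """Radius of a cover centered on ``center``.

    Let d1 be the distance to the nearest opposite-class point (infinity
    if there is none) and d2 the distance to the farthest same-class
    point closer than d1. The default "midpoint" rule returns
    (d1 + d2)/2, placing the boundary halfway between the last friendly
    point and the nearest enemy; "tight" returns d2, hugging the
    friendly points. With no enemies the radius is d2 (all friends
    covered). Either way no enemy point can fall within the radius.
    """
    center = np.asarray(center, dtype=float)
    same = np.atleast_2d(np.asarray(same, dtype=float))
    if same.size == 0:
        raise ValueError("cover needs at least one same-class point")
    if mode not in ("midpoint", "tight"):
        raise ValueError(f"radius mode must be 'midpoint' or 'tight', got {mode!r}")
    d_same = np.linalg.norm(same - center, axis=1)
    enemy = np.asarray(enemy, dtype=float)
    if enemy.size == 0:
        return float(d_same.max())
    d1 = float(np.linalg.norm(np.atleast_2d(enemy) - center, axis=1).min())
    eligible = d_same[d_same < d1]
    # the center itself is a same-class point at distance 0 < d1
    d2 = float(eligible.max()) if eligible.size else 0.0
    if mode == "tight":
        return d2
    return (d1 + d2) / 2.0


def train(features, labels=None, R: float | str = "auto",
          radius_mode: str = "midpoint") -> CoverModel:
    """Build a cover model from a labelled feature table.

    ``features`` is either an (n_samples, n_features) array with
    ``labels`` given separately, or any object with ``values`` whose
    last column is the 0/1 label (e.g. a DataFrame of feature rows).

    Construction alternates between the classes, class 0 first: among
    the still-uncovered points of the class, the member nearest (in
    lifted Euclidean distance) to their mean is the center — ties go to
    the lowest row index — and the radius comes from
    :func:`cover_radius` against *all* opposite-class training points.
    Each round covers at least the center itself, so the loop
    terminates.
    """
    if labels is None:
        table = np.asarray(getattr(features, "values", features), dtype=float)
        X, y = table[:, :-1], table[:, -1]
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=float)
    X = np.atleast_2d(X)
    y = y.astype(int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on sample count")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"training requires both classes 0 and 1, got labels {classes.tolist()}"
        )
    dup_conflict = False
    _, inv = np.unique(X, axis=0, return_inverse=True)
    for g in range(inv.max() + 1):
        if np.unique(y[inv == g]).size > 1:
            dup_conflict = True
    if dup_conflict:
        warnings.warn(
            "duplicate feature vectors carry conflicting labels; such points "
            "may sit on cover boundaries",
            UserWarning,
            stacklevel=2,
        )

    mins, ranges = normalize_fit(X)
    Z = normalize_apply(X, mins, ranges)
    norms = np.linalg.norm(Z, axis=1)
    R_val = float(norms.max()) if R == "auto" else float(R)
    if R_val < norms.max() - 1e-12:
        raise ValueError("R smaller than the largest normalized sample norm")
    lifted = np.stack([sphere_project(z, R_val) for z in Z])

    covered = np.zeros(X.shape[0], dtype=bool)
    covers: list[Cover] = []
    while not covered.all():
        for cls in (0, 1):
            idx = np.flatnonzero((y == cls) & ~covered)
            if idx.size == 0:
                continue
            c_set = lifted[idx]
            mean = c_set.mean(axis=0)
            # nearest to mean; np.argmin takes the lowest index on ties
            center_pos = idx[int(np.argmin(np.linalg.norm(c_set - mean, axis=1)))]
            center = lifted[center_pos]
            enemy = lifted[y != cls]
            radius = cover_radius(center, c_set, enemy, mode=radius_mode)
            inside = np.linalg.norm(c_set - center, axis=1) <= radius
            covered[idx[inside]] = True
            covers.append(
                Cover(
                    center=center,
                    radius=radius,
                    label=cls,
                    member_count=int(inside.sum()),
                )
            )
    return CoverModel(
        covers=covers,
        feature_mins=mins,
        feature_ranges=ranges,
        R=R_val,
        radius_mode=radius_mode,
    )


def _lift_query(model: CoverModel, x) -> np.ndarray:
    z = normalize_apply(x, model.feature_mins, model.feature_ranges, clip=True)
    norm = float(np.linalg.norm(z))
    if norm > model.R:
        # unseen points beyond the training sphere are clipped radially
        z = z * (model.R / norm)
    return sphere_project(z, model.R)


def decide(model: CoverModel, x) -> Decision:
    """Three-way decision for one raw feature vector.

    Normalizes with the training parameters (clipping into [0, 1]),
    lifts onto the training sphere, and checks cover membership: inside
    covers of exactly one class -> that class; inside both classes'
    covers, or inside none -> boundary (abstain).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"expected a feature vector of length {model.n_features}, "
            f"got shape {x.shape}"
        )
    point = _lift_query(model, x)
    inside = {0: False, 1: False}
    for cover in model.covers:
        if not inside[cover.label]:
            if np.linalg.norm(point - cover.center) <= cover.radius:
                inside[cover.label] = True
    if inside[0] and not inside[1]:
        return Decision(region="POS", predicted_label=0)
    if inside[1] and not inside[0]:
        return Decision(region="NEG", predicted_label=1)
    return Decision(region="BND", predicted_label=BOUNDARY)
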