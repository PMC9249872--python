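"""Feature-importance tensors and their spatial / temporal / wavelength views.

Importance follows the loss-function-change idea: a parameter matters to the
extent that removing its contribution degrades the model's loss.  Two
estimators implement the contract:

* ``native`` — the boosted trees' per-column split gain, i.e. the total
  training-loss reduction attributed to splits on that column, summed over
  the one-vs-one ensemble's binary models.  Free, deterministic, and the
  default.
* ``permutation`` — a seeded surrogate that permutes a column (or a batch of
  columns) in a held-out matrix and measures the multiclass log-loss
  increase.  Slower, model-agnostic, and used to cross-check the native
  scores.

Either way the scores are clipped at zero and normalized so that all 61,250
spatiotemporal entries plus the heart-rate scalar sum to 100 (percent).  The
tensor is then marginalized into per-feature spatial maps, a per-pulse-frame
temporal profile, per-feature (wavelength) totals, per-class-pair maps from
independently retrained binary models, named-region statistics, and
metadata-grouped (e.g. per-gender) analyses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import log_loss

from tstms.classify import Dataset, OvOModel, train_ovo
from tstms.features import FEATURE_VECTOR_LENGTH, SPATIOTEMPORAL_FEATURES
from tstms.pulse_events import N_PULSE_FRAMES
from tstms.recording import GRID_SHAPE

log = logging.getLogger(__name__)

_TENSOR_SHAPE = (len(SPATIOTEMPORAL_FEATURES), N_PULSE_FRAMES, *GRID_SHAPE)


@dataclass
class ImportanceTensor:
    """Percent importance per (feature, pulse frame, row, col) plus F8.

    All entries are nonnegative and, together with ``f8_value``, sum to 100.
    """

    values: np.ndarray
    f8_value: float

    def __post_init__(self) -> None:
        if self.values.shape != _TENSOR_SHAPE:
            raise ValueError(f"importance tensor must be {_TENSOR_SHAPE}")
        if np.any(self.values < 0) or self.f8_value < 0:
            raise ValueError("importances must be nonnegative")
        total = self.values.sum() + self.f8_value
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"importances must sum to 100, got {total}")


@dataclass
class RoiSpec:
    """Named rectangular regions of interest on the 50x35 grid.

    Boxes are ``(row0, col0, row1, col1)`` with exclusive upper bounds; they
    must fit the grid and may not overlap one another.
    """

    regions: dict[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        occupancy = np.zeros(GRID_SHAPE, dtype=int)
        for name, (r0, c0, r1, c1) in self.regions.items():
            if not (0 <= r0 < r1 <= GRID_SHAPE[0] and 0 <= c0 < c1 <= GRID_SHAPE[1]):
                raise ValueError(f"ROI {name} outside the grid")
            occupancy[r0:r1, c0:c1] += 1
        if occupancy.max() > 1:
            raise ValueError("ROIs may not overlap")

    def mask(self, name: str) -> np.ndarray:
        r0, c0, r1, c1 = self.regions[name]
        m = np.zeros(GRID_SHAPE, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m


def default_rois() -> RoiSpec:
    """Anatomically plausible boxes: forehead, eyes, cheeks, mouth."""
    return RoiSpec(
        regions={
            "forehead": (3, 7, 14, 28),
            "left_eye": (16, 5, 22, 14),
            "right_eye": (16, 21, 22, 30),
            "left_cheek": (24, 4, 34, 13),
            "right_cheek": (24, 22, 34, 31),
            "mouth": (36, 10, 43, 25),
        }
    )


def _normalize(raw: np.ndarray) -> ImportanceTensor:
    raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = raw.sum()
    if total == 0:
        raise ValueError("all importances are zero; nothing to normalize")
    pct = raw / total * 100.0
    tensor = pct[:-1].reshape(_TENSOR_SHAPE)
    # absorb any float residue so the invariant holds exactly
    f8 = 100.0 - tensor.sum()
    return ImportanceTensor(values=tensor, f8_value=max(f8, 0.0))


def _native_gains(model: OvOModel) -> np.ndarray:
    gains = np.zeros(FEATURE_VECTOR_LENGTH)
    for booster in model.models.values():
        gains += booster.feature_importance(importance_type="gain")
    return gains


def permutation_importance_columns(
    model: OvOModel,
    X: np.ndarray,
    y: np.ndarray,
    column_groups: list[np.ndarray],
    seed: int = 0,
) -> np.ndarray:
    """Loss increase when each column group is independently permuted.

    The baseline is the multiclass log-loss of the model's averaged OvO
    probabilities on ``(X, y)``; each group's columns are shuffled with a
    seeded generator (rows permuted jointly within the group) and the loss
    recomputed.  Returns one score per group (may be negative before
    clipping).
    """
    rng = np.random.default_rng(seed)
    classes = model.classes
    y_idx = np.searchsorted(np.array(classes), np.asarray(y))
    base = log_loss(y_idx, model.predict_proba(X), labels=range(len(classes)))
    scores = np.empty(len(column_groups))
    for g, cols in enumerate(column_groups):
        Xp = X.copy()
        perm = rng.permutation(len(X))
        Xp[:, cols] = Xp[perm][:, cols]
        scores[g] = (
            log_loss(y_idx, model.predict_proba(Xp), labels=range(len(classes)))
            - base
        )
    return scores


def lfc_importance(
    model: OvOModel,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    mode: str = "native",
    seed: int = 0,
) -> ImportanceTensor:
    """Per-parameter loss-change importance, normalized to percent.

    ``native`` reads the trees' split gains (loss reduction per column);
    ``permutation`` permutes every column independently on ``(X, y)`` —
    exact but expensive at 61k columns, intended for small models and for
    cross-checking the native scores.  Constant or never-used columns get
    importance 0.
    """
    if mode == "native":
        raw = _native_gains(model)
    elif mode == "permutation":
        if X is None or y is None:
            raise ValueError("permutation mode needs X and y")
        groups = [np.array([j]) for j in range(X.shape[1])]
        raw = permutation_importance_columns(model, X, y, groups, seed=seed)
    else:
        raise ValueError(f"unknown importance mode {mode!r}")
    return _normalize(raw)


def spatial_maps(it: ImportanceTensor) -> dict:
    """Per-feature 50x35 maps (summed over pulse frames) and their percents.

    ``summary`` is the mean of the seven per-feature maps; the spatial total
    is everything that is not the heart-rate scalar: 100 - F8's percent.
    """
    maps = {
        name: it.values[i].sum(axis=0)
        for i, name in enumerate(SPATIOTEMPORAL_FEATURES)
    }
    percents = {
        name: float(it.values[i].sum())
        for i, name in enumerate(SPATIOTEMPORAL_FEATURES)
    }
    summary = np.mean([maps[n] for n in SPATIOTEMPORAL_FEATURES], axis=0)
    return {
        "maps": maps,
        "summary": summary,
        "percents": percents,
        "spatial_total_percent": 100.0 - it.f8_value,
        "f8_percent": it.f8_value,
    }


def temporal_profile(it: ImportanceTensor) -> np.ndarray:
    """Total importance per pulse frame (length 5, sums to 100 - F8%)."""
    return it.values.sum(axis=(0, 2, 3))


def wavelength_totals(it: ImportanceTensor) -> dict[str, float]:
    """Overall importance per feature after spatiotemporal summation."""
    totals = {
        name: float(it.values[i].sum())
        for i, name in enumerate(SPATIOTEMPORAL_FEATURES)
    }
    totals["F8"] = it.f8_value
    return totals


def pairwise_maps(
    ds: Dataset,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], dict]:
    """Independent binary retraining per class pair → per-pair spatial maps.

    For k classes this yields k(k-1)/2 maps; each entry carries the pair's
    spatial summary map and its spatiotemporal percent (the remainder to 100
    is that pair's F8 share).  Pairs without data on both sides are skipped
    with a warning.
    """
    out = {}
    for c1, c2 in itertools.combinations(ds.classes, 2):
        sel = np.flatnonzero((ds.y == c1) | (ds.y == c2))
        if len(set(ds.y[sel])) < 2:
            log.warning("pair (%s, %s) lacks data; skipped", c1, c2)
            continue
        model = train_ovo(ds.X[sel], ds.y[sel], hyperparams=hyperparams, seed=seed)
        it = lfc_importance(model)
        view = spatial_maps(it)
        out[(c1, c2)] = {
            "summary": view["summary"],
            "spatiotemporal_percent": view["spatial_total_percent"],
            "f8_percent": view["f8_percent"],
        }
    return out


def roi_stats(
    mean_map: np.ndarray,
    rois: RoiSpec,
    fold_maps: list[np.ndarray],
    face_mask: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean ± SD importance per ROI and a bootstrap ROI-vs-rest comparison.

    The mean is over ROI pixels of ``mean_map``; the SD is the across-fold
    dispersion of the per-fold ROI means.  The p-value is a two-sided
    bootstrap (over folds, ``n_boot`` seeded resamples) of the difference
    between the ROI mean and the rest-of-face mean.
    """
    if len(fold_maps) < 2:
        raise ValueError("need at least 2 fold maps for dispersion")
    face = np.ones(GRID_SHAPE, dtype=bool) if face_mask is None else face_mask
    rng = np.random.default_rng(seed)
    out = {}
    for name in rois.regions:
        m = rois.mask(name)
        if not m.any():
            raise ValueError(f"ROI {name} is empty")
        rest = face & ~m
        fold_in = np.array([fm[m & face].mean() for fm in fold_maps])
        fold_out = np.array([fm[rest].mean() for fm in fold_maps])
        diffs = fold_in - fold_out
        obs = diffs.mean()
        idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
        boot = diffs[idx].mean(axis=1)
        # two-sided bootstrap p for mean difference != 0
        p = 2.0 * min(np.mean(boot <= 0), np.mean(boot >= 0))
        out[name] = {
            "mean": float(mean_map[m & face].mean()),
            "sd": float(fold_in.std(ddof=1)),
            "rest_mean": float(mean_map[rest].mean()),
            "diff": float(obs),
            "p_value": float(min(max(p, 1.0 / n_boot), 1.0)),
        }
    return out


def grouped_analysis(
    ds: Dataset,
    group_by: str = "gender",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Retrain and map importance separately per metadata group.

    Currently the only supported key is ``gender``.  Groups with fewer than
    two subjects are skipped (LOOCV-style analyses are meaningless there).
    """
    if group_by != "gender":
        raise ValueError(f"unknown group-by key {group_by!r}")
    if ds.gender is None:
        raise ValueError("dataset carries no gender metadata")
    out = {}
    for g in np.unique(ds.gender):
        sel = np.flatnonzero(np.asarray(ds.gender) == g)
        if len(np.unique(ds.subjects[sel])) < 2:
            log.warning("group %s has fewer than 2 subjects; skipped", g)
            continue
        model = train_ovo(ds.X[sel], ds.y[sel], hyperparams=hyperparams, seed=seed)
        it = lfc_importance(model)
        out[str(g)] = {"tensor": it, **spatial_maps(it)}
    return out
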