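"""Functional-tissue discrimination from texture.

The discrimination chain mirrors how functioning parenchyma is separated
from oedema/congestion on CT texture: patches of the remnant parenchyma are
featurised, features are standardised, the most informative first-order
features are selected by information gain (with a Student t-test screen
reported alongside and an exploratory k-means subgrouping), and a
multivariate logistic regression classifies each patch as functional or
oedematous. Integrating the functional patches over the remnant converts a
post-modulation study into a functional-remnant volume (FRFx) in cc.

The spatial unit is the non-overlapping cubic patch (default 4^3 voxels =
1 cc at 2.5 mm): large enough for stable texture statistics, small enough to
localise an oedema rim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .radiomics.base import StandardizationParams, standardize
from .radiomics.firstorder import FIRST_ORDER_NAMES, first_order_features_batch
from .radiomics.catalogue import AnalysisMask, flr_analysis_mask
from .types import ImageVolume, PhantomCase, Truth

__all__ = [
    "ClassifierConfig",
    "SelectionReport",
    "LogisticModel",
    "FunctionalMap",
    "information_gain",
    "screen_ttest",
    "kmeans_profiles",
    "fit_logistic",
    "harvest_patches",
    "train_functional_classifier",
    "classify_patches",
    "estimate_frfx",
]

FUNCTIONAL, OEDEMA = 1, 0  # binary patch labels

#: First-order features eligible for patch-level selection. Extensive
#: features (energy sums) and raw extremes scale with the number of
#: in-mask voxels, so on partially covered boundary patches they encode
#: patch coverage rather than tissue texture; excluding them keeps the
#: classifier honest when there is no real texture contrast.
INTENSIVE_FIRST_ORDER: tuple[str, ...] = tuple(
    n
    for n in FIRST_ORDER_NAMES
    if n
    not in {
        "firstorder_Energy",
        "firstorder_TotalEnergy",
        "firstorder_Minimum",
        "firstorder_Maximum",
    }
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the patch-classification chain."""

    patch_size: int = 4
    top_k: int = 5
    bin_width: float = 25.0
    l2_strength: float = 1.0
    coverage_threshold: float = 0.5
    purity_threshold: float = 0.9
    min_patches_per_class: int = 10
    n_ig_bins: int = 10
    threshold: float = 0.5
    seed: int = 0
    selection_pool: tuple[str, ...] = INTENSIVE_FIRST_ORDER


# ---------------------------------------------------------------------------
# feature selection statistics
# ---------------------------------------------------------------------------

def information_gain(
    feature_values: np.ndarray, binary_labels: np.ndarray, n_bins: int = 10
) -> float:
    """Mutual information (bits) between an equal-frequency-binned feature
    and a binary label: IG = H(Y) - sum_b p(b) H(Y | b).

    Equal-frequency binning makes the result invariant to strictly monotone
    transforms of the feature.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(binary_labels)
    if x.shape != y.shape:
        raise ValueError("feature and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")

    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, x, side="right")

    def _h(labels: np.ndarray) -> float:
        p = np.bincount(np.searchsorted(classes, labels)) / labels.size
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_y = _h(y)
    h_cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        h_cond += sel.mean() * _h(y[sel])
    return max(0.0, h_y - h_cond)


def screen_ttest(
    matrix: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance Student t per feature column.

    Returns (t, p) arrays; df = n1 + n2 - 2, two-sided p. Zero pooled
    variance yields t = 0 for equal means and +/-inf for unequal means.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two groups required")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    diff = a.mean(axis=0) - b.mean(axis=0)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def kmeans_profiles(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exploratory k-means subgrouping of standardised activation profiles.

    Returns (assignments, centroids, inertia); best of ``n_init`` k-means++
    restarts, deterministic given the seed.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available rows")
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed
    ).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Fitted L2-penalised logistic classifier over selected features."""

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    standardization: StandardizationParams
    threshold: float = 0.5
    l2_strength: float = 1.0
    seed: int = 0
    bin_width: float = 25.0
    catalogue_version: str = "1.0"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError("one coefficient per feature name required")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def predict_proba(self, X_selected: np.ndarray) -> np.ndarray:
        """P(functional) for rows already standardised and column-selected."""
        z = np.asarray(X_selected, dtype=np.float64) @ self.coefficients + self.intercept
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def to_json(self) -> str:
        d = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "l2_strength": self.l2_strength,
            "seed": self.seed,
            "bin_width": self.bin_width,
            "catalogue_version": self.catalogue_version,
            "standardization": {
                "names": self.standardization.names,
                "mean": self.standardization.mean.tolist(),
                "sd": self.standardization.sd.tolist(),
                "dropped": self.standardization.dropped,
            },
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        sp = StandardizationParams(
            names=d["standardization"]["names"],
            mean=np.array(d["standardization"]["mean"]),
            sd=np.array(d["standardization"]["sd"]),
            dropped=d["standardization"]["dropped"],
        )
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            standardization=sp,
            threshold=d["threshold"],
            l2_strength=d["l2_strength"],
            seed=d["seed"],
            bin_width=d["bin_width"],
            catalogue_version=d["catalogue_version"],
        )


def fit_logistic(
    matrix_selected: np.ndarray,
    labels: np.ndarray,
    l2_strength: float = 1.0,
    seed: int = 0,
    max_iter: int = 5000,
) -> tuple[np.ndarray, float]:
    """Maximise the L2-penalised Bernoulli log-likelihood (lbfgs).

    Inputs are standardised feature columns; returns (coefficients,
    intercept). Raises on non-convergence.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    clf = LogisticRegression(
        C=1.0 / max(l2_strength, 1e-12),
        solver="lbfgs",
        tol=1e-8,
        max_iter=max_iter,
        random_state=seed,
    ).fit(np.asarray(matrix_selected, dtype=np.float64), y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= max_iter:
        raise RuntimeError(
            f"logistic fit did not converge within {max_iter} iterations"
        )
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


# ---------------------------------------------------------------------------
# patch machinery
# ---------------------------------------------------------------------------

def _tile(volume: np.ndarray, patch_size: int) -> np.ndarray:
    """Reshape a 3-D grid into (n_patches, patch_size**3) rows."""
    nx, ny, nz = volume.shape
    ps = patch_size
    if nx % ps or ny % ps or nz % ps:
        raise ValueError(f"patch size {ps} must divide the grid {volume.shape}")
    v = volume.reshape(nx // ps, ps, ny // ps, ps, nz // ps, ps)
    return v.transpose(0, 2, 4, 1, 3, 5).reshape(-1, ps**3)


def _patch_grid_shape(shape: Sequence[int], ps: int) -> tuple[int, int, int]:
    return tuple(s // ps for s in shape)


def _patch_feature_matrix(
    vox: np.ndarray, mask: np.ndarray, cfg: ClassifierConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order feature rows for every patch with >= 1 in-mask voxel.

    Returns (features (P, 19), coverage per patch, patch index of each row).
    """
    vals = _tile(np.where(mask, vox, np.nan).astype(np.float64), cfg.patch_size)
    cov = 1.0 - np.isnan(vals).mean(axis=1)
    nonempty = cov > 0
    feats = first_order_features_batch(vals[nonempty], cfg.bin_width)
    X = np.column_stack([feats[n] for n in FIRST_ORDER_NAMES])
    return X, cov, np.flatnonzero(nonempty)


@dataclass
class SelectionReport:
    """Feature-selection audit: IG ranking, t-screen, k-means exploration."""

    feature_names: list[str]
    information_gain_bits: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    ranked: list[str]
    chosen: list[str]
    n_functional: int
    n_oedema: int
    kmeans_inertia: float = float("nan")
    kmeans_truth_agreement: float = float("nan")

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "information_gain_bits": self.information_gain_bits,
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "chosen": [n in self.chosen for n in self.feature_names],
            }
        ).sort_values("information_gain_bits", ascending=False, ignore_index=True)


def harvest_patches(
    cases: Sequence[PhantomCase], cfg: ClassifierConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled training patches from phantom cases with truth masks.

    Functional patches come from the pre-study FLR (parenchyma before
    modulation is taken as functional) and from truth-functional post-study
    regions; oedema patches from truth-oedema regions. Post-study patches
    must be pure (>= ``purity_threshold`` of one truth class) and all patches
    need coverage >= ``coverage_threshold``.
    """
    rows, labels = [], []
    for case in cases:
        for timepoint, (img, seg) in (("pre", case.pre), ("post", case.post)):
            if img is None:
                raise ValueError(f"{case.meta.case_id}/{timepoint}: no rendered image")
            if seg.truth is None:
                raise ValueError(f"{case.meta.case_id}: truth mask required for training")
            amask = flr_analysis_mask(seg, case.meta.case_id, timepoint)
            X, cov, idx = _patch_feature_matrix(img.voxels, amask.mask, cfg)
            covered = cov[idx] >= cfg.coverage_threshold
            frac_oed = _tile(
                np.where(amask.mask, (seg.truth == Truth.OEDEMA), np.nan).astype(
                    np.float64
                ),
                cfg.patch_size,
            )
            frac = np.nanmean(frac_oed[idx], axis=1)
            pure_oed = covered & (frac >= cfg.purity_threshold)
            pure_fun = covered & (frac <= 1.0 - cfg.purity_threshold)
            rows.append(X[pure_fun])
            labels.append(np.full(int(pure_fun.sum()), FUNCTIONAL))
            rows.append(X[pure_oed])
            labels.append(np.full(int(pure_oed.sum()), OEDEMA))
    X = np.vstack(rows)
    y = np.concatenate(labels)
    n_fun, n_oed = int((y == FUNCTIONAL).sum()), int((y == OEDEMA).sum())
    if min(n_fun, n_oed) < cfg.min_patches_per_class:
        raise ValueError(
            f"too few training patches: functional={n_fun}, oedema={n_oed} "
            f"(need >= {cfg.min_patches_per_class} each)"
        )
    return X, y


def train_functional_classifier(
    cases: Sequence[PhantomCase],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[SelectionReport, LogisticModel]:
    """Full training chain: harvest -> standardise -> IG-select -> logistic.

    Selection is restricted to the first-order family; ranking ties break
    lexicographically on the feature name. An exploratory 2-group k-means on
    the standardised profiles is reported (truth agreement as max-matching
    accuracy), but never feeds the model.
    """
    X_raw, y = harvest_patches(cases, cfg)
    Z, params = standardize(X_raw, list(FIRST_ORDER_NAMES))
    ig = np.array(
        [information_gain(Z[:, j], y, cfg.n_ig_bins) for j in range(Z.shape[1])]
    )
    t, p = screen_ttest(Z, y)
    pool = [j for j, n in enumerate(params.names) if n in cfg.selection_pool]
    order = sorted(pool, key=lambda j: (-ig[j], params.names[j]))
    ranked = [params.names[j] for j in order]
    chosen = ranked[: cfg.top_k]
    cols = [params.names.index(n) for n in chosen]

    coef, intercept = fit_logistic(Z[:, cols], y, cfg.l2_strength, cfg.seed)

    assign, _, inertia = kmeans_profiles(Z, k=2, seed=cfg.seed)
    agree = max(
        float((assign == y).mean()), float((assign == (1 - y)).mean())
    )

    report = SelectionReport(
        feature_names=params.names,
        information_gain_bits=ig,
        t_statistic=t,
        p_value=p,
        ranked=ranked,
        chosen=chosen,
        n_functional=int((y == FUNCTIONAL).sum()),
        n_oedema=int((y == OEDEMA).sum()),
        kmeans_inertia=inertia,
        kmeans_truth_agreement=agree,
    )
    model = LogisticModel(
        feature_names=chosen,
        coefficients=coef,
        intercept=intercept,
        standardization=params,
        threshold=cfg.threshold,
        l2_strength=cfg.l2_strength,
        seed=cfg.seed,
        bin_width=cfg.bin_width,
    )
    return report, model


# ---------------------------------------------------------------------------
# volume classification
# ---------------------------------------------------------------------------

@dataclass
class FunctionalMap:
    """Patch-level classification of a remnant volume.

    ``probability`` is P(functional) on the patch grid (NaN where a patch has
    no parenchyma); ``functional`` the thresholded labels with low-coverage
    patches filled from their nearest classified patch; ``frfx_cc`` the
    integrated functional parenchyma volume.
    """

    probability: np.ndarray
    functional: np.ndarray
    coverage: np.ndarray
    patch_size: int
    frfx_cc: float
    analysable_cc: float


def classify_patches(
    post_volume: ImageVolume,
    analysis_mask: AnalysisMask,
    model: LogisticModel,
    patch_size: int = 4,
    coverage_threshold: float = 0.5,
) -> FunctionalMap:
    """Tile the analysis mask into congruent cubes and classify each.

    Patches with parenchyma coverage >= ``coverage_threshold`` are classified
    by the logistic model; parenchyma in lower-coverage patches inherits the
    label of the nearest classified patch, so every analysable voxel is
    assigned. ``frfx_cc`` sums the in-mask volume of functional patches.
    """
    cfg = ClassifierConfig(
        patch_size=patch_size,
        bin_width=model.bin_width,
        coverage_threshold=coverage_threshold,
        threshold=model.threshold,
    )
    X, cov, idx = _patch_feature_matrix(
        post_volume.voxels, analysis_mask.mask, cfg
    )
    pshape = _patch_grid_shape(post_volume.shape, patch_size)
    n_patches = int(np.prod(pshape))

    classified = cov[idx] >= coverage_threshold
    if not classified.any():
        raise ValueError("no patch reaches the coverage threshold")

    all_names = list(FIRST_ORDER_NAMES)
    keep_cols = [all_names.index(n) for n in model.standardization.names]
    Z = model.standardization.transform(X[:, keep_cols])
    sel = [model.standardization.names.index(n) for n in model.feature_names]
    proba = model.predict_proba(Z[:, sel])

    prob_grid = np.full(n_patches, np.nan)
    prob_grid[idx[classified]] = proba[classified]
    func_grid = np.zeros(n_patches, dtype=bool)
    func_grid[idx[classified]] = proba[classified] >= model.threshold

    # low-coverage parenchyma inherits the nearest classified patch's label
    centres = np.stack(np.unravel_index(np.arange(n_patches), pshape), axis=1)
    tree = cKDTree(centres[idx[classified]])
    low = idx[~classified]
    if low.size:
        _, nn = tree.query(centres[low])
        func_grid[low] = func_grid[idx[classified][nn]]
        prob_grid[low] = prob_grid[idx[classified][nn]]

    in_mask_counts = np.zeros(n_patches)
    in_mask_counts[idx] = cov[idx] * patch_size**3
    voxcc = np.prod(post_volume.spacing) / 1000.0
    frfx_cc = float(in_mask_counts[func_grid].sum() * voxcc)
    analysable_cc = float(in_mask_counts.sum() * voxcc)

    return FunctionalMap(
        probability=prob_grid.reshape(pshape),
        functional=func_grid.reshape(pshape),
        coverage=(in_mask_counts / patch_size**3).reshape(pshape),
        patch_size=patch_size,
        frfx_cc=frfx_cc,
        analysable_cc=analysable_cc,
    )


def estimate_frfx(
    case: PhantomCase,
    model: LogisticModel,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, float]:
    """Estimated functional remnant volume (cc) at both timepoints."""
    out = []
    for timepoint, (img, seg) in (("pre", case.pre), ("post", case.post)):
        if img is None:
            raise ValueError(f"{case.meta.case_id}/{timepoint}: no rendered image")
        amask = flr_analysis_mask(seg, case.meta.case_id, timepoint)
        fmap = classify_patches(
            img, amask, model, cfg.patch_size, cfg.coverage_threshold
        )
        out.append(fmap.frfx_cc)
    return out[0], out[1]
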