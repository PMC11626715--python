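"""Stacked ensemble spatial regression for isoscape construction.

The regression maps predictor rasters plus point observations of
bioavailable 87Sr/86Sr to a continuous isoscape with a per-pixel
uncertainty grid.  The framework:

* variable selection by random-forest permutation importance against
  permuted decoy columns;
* spatial position encoded as distance-to-anchor ("oblique distance")
  covariates compressed by PCA, so nonspatial learners can capture
  spatial dependence;
* a stacked ensemble: several base learners (random forest, gradient
  boosting, support-vector, elastic-net linear, optionally a neural
  network) fit independently, combined by a linear meta-learner whose
  weights are estimated on spatially blocked held-out predictions;
* per-pixel prediction errors from the central 67% quantile interval of
  held-out residuals pooled over nearest training neighbours, combined
  with an intra-site variance floor;
* spatial block cross-validation (k-means blocks of point coordinates)
  for honest skill estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.compose import TransformedTargetRegressor
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNetCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from isomigrate import geo
from isomigrate.grid import GeoGrid, GridSpec, Isoscape, PredictorStack

log = logging.getLogger(__name__)

LEARNER_KINDS = (
    "random_forest",
    "gradient_boosting",
    "support_vector",
    "neural_network",
    "elastic_net",
)
#: neural network is implemented but off by default (high variance at
#: desk scale); pass it explicitly for five-learner parity.
DEFAULT_LEARNERS = (
    "random_forest", "gradient_boosting", "support_vector", "elastic_net",
)


def _make_learner(kind: str, seed: int):
    if kind == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed,
                                     n_jobs=1)
    if kind == "gradient_boosting":
        from xgboost import XGBRegressor
        return XGBRegressor(n_estimators=200, learning_rate=0.1, max_depth=4,
                            random_state=seed, n_jobs=1, verbosity=0)
    if kind == "support_vector":
        # target is standardized too: SVR's epsilon tube is scale-dependent
        # and isotope ratios span ~0.07 in absolute units
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), SVR(C=10.0, gamma="scale")),
            transformer=StandardScaler(),
        )
    if kind == "elastic_net":
        return make_pipeline(
            StandardScaler(),
            ElasticNetCV(l1_ratio=[0.1, 0.5, 0.9, 1.0], cv=5,
                         random_state=seed, max_iter=5000),
        )
    if kind == "neural_network":
        return TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(),
                MLPRegressor(hidden_layer_sizes=(32, 16), max_iter=2000,
                             random_state=seed),
            ),
            transformer=StandardScaler(),
        )
    raise ValueError(f"unknown learner kind {kind!r}; "
                     f"choose from {LEARNER_KINDS}")


@dataclass(frozen=True)
class SpatialFeatureSpec:
    """Parameters of the oblique-distance spatial covariates."""

    n_anchor_points: int = 25
    n_pca_components: int = 8
    anchor_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_anchor_points < 1:
            raise ValueError("need at least one anchor point")
        if self.n_pca_components > self.n_anchor_points:
            raise ValueError("n_pca_components must be <= n_anchor_points")


@dataclass
class SpatialFeatures:
    """Distance-derived covariates on the grid and at training points."""

    stack: PredictorStack
    train_values: np.ndarray  # (n_train, n_components)
    anchors: np.ndarray       # (n_anchor, 2) lon/lat
    names: list[str]


@dataclass
class CvReport:
    rmse: float
    r2: float
    fold_assignments: np.ndarray

    def to_dict(self) -> dict:
        return {"rmse": float(self.rmse), "r2": float(self.r2),
                "n_folds": int(len(np.unique(self.fold_assignments)))}


@dataclass
class ErrorModel:
    """Per-pixel prediction SD for an isoscape."""

    quantile_level: float
    intra_site_sd: float
    sd_grid: GeoGrid


@dataclass
class EnsembleModel:
    """A fitted stacked ensemble plus everything needed to predict.

    The meta prediction is exactly
    ``intercept + sum(weight_l * base_prediction_l)``.
    """

    selected_predictors: list[str]
    learners: dict[str, object]
    meta_intercept: float
    meta_weights: dict[str, float]
    meta_tvalues: dict[str, float]
    spatial: SpatialFeatures | None
    train_coords: np.ndarray
    train_residuals: np.ndarray  # held-out (blocked) meta residuals
    cv_report: CvReport
    crs: str
    format_version: int = 1

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        pred = np.full(X.shape[0], self.meta_intercept, dtype=float)
        for name, est in self.learners.items():
            pred += self.meta_weights[name] * np.asarray(est.predict(X),
                                                         dtype=float)
        return pred

    def save(self, path) -> None:
        import joblib
        joblib.dump({"format_version": self.format_version, "model": self}, path)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        import joblib
        bundle = joblib.load(path)
        if bundle.get("format_version") != 1:
            raise ValueError("unsupported model bundle version")
        return bundle["model"]


def _points_to_cells(training: pd.DataFrame, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    for lon, lat in zip(training["lon"], training["lat"]):
        r, c = spec.index_of(lon, lat)
        rows.append(r)
        cols.append(c)
    return np.array(rows), np.array(cols)


def extract_predictors(training: pd.DataFrame, stack: PredictorStack) -> np.ndarray:
    """Matrix of predictor values at each training point's cell."""
    rows, cols = _points_to_cells(training, stack.spec)
    return np.column_stack([stack[n].values[rows, cols] for n in stack.names])


def select_predictors(
    training: pd.DataFrame,
    stack: PredictorStack,
    n_keep: int | str = "auto",
    seed: int = 0,
    n_decoys: int = 5,
) -> list[str]:
    """Rank predictors by forest permutation importance; screen by decoys.

    ``n_keep="auto"`` keeps predictors whose permutation importance
    exceeds the maximum importance among ``n_decoys`` permuted decoy
    columns (pure noise with realistic marginals); an integer keeps the
    top ``n_keep`` in importance order.
    """
    if len(stack) == 0:
        raise ValueError("empty predictor stack")
    n_points = len(training)
    if n_points < 20:
        raise ValueError("need at least 20 training points")
    if n_keep == "auto" and n_points < len(stack):
        raise ValueError(
            "fewer training points than predictors; 'auto' selection is "
            "unreliable — pass an explicit n_keep"
        )
    rng = np.random.default_rng(seed)
    X = extract_predictors(training, stack)
    y = training["ratio"].to_numpy(dtype=float)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]

    decoys = np.column_stack([
        rng.permutation(X[:, rng.integers(0, X.shape[1])])
        for _ in range(n_decoys)
    ])
    X_aug = np.column_stack([X, decoys])
    # importance on a holdout split: in-sample permutation importance
    # flatters smooth but uninformative layers
    n_obs = X_aug.shape[0]
    perm = rng.permutation(n_obs)
    n_fit = max(int(0.7 * n_obs), n_obs - 200)
    fit_idx, val_idx = perm[:n_fit], perm[n_fit:]
    rf = RandomForestRegressor(n_estimators=300, random_state=seed, n_jobs=1)
    rf.fit(X_aug[fit_idx], y[fit_idx])
    imp = permutation_importance(
        rf, X_aug[val_idx], y[val_idx], n_repeats=10,
        random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
    ).importances_mean
    real_imp = imp[: X.shape[1]]
    decoy_max = imp[X.shape[1]:].max() if n_decoys > 0 else -np.inf
    order = np.argsort(real_imp)[::-1]
    names = stack.names
    if n_keep == "auto":
        kept = [names[i] for i in order if real_imp[i] > decoy_max]
        if not kept:
            log.warning("no predictor beat the decoy threshold; keeping the "
                        "single most important")
            kept = [names[order[0]]]
        return kept
    n_keep = int(n_keep)
    if not 1 <= n_keep <= len(names):
        raise ValueError("n_keep out of range")
    return [names[i] for i in order[:n_keep]]


def build_spatial_features(
    training: pd.DataFrame,
    grid: GridSpec,
    spec: SpatialFeatureSpec,
) -> SpatialFeatures:
    """Oblique-distance covariates: distances to anchor points, PCA-reduced.

    Anchors are subsampled from the training points (``anchor_seed``).
    With a single anchor the layer is the raw distance to it and PCA is
    a no-op.  The PCA is fit on the training-point distance matrix, so
    component scores at training locations are exactly orthogonal.
    """
    n = len(training)
    if n < spec.n_anchor_points:
        raise ValueError("need at least n_anchor_points training points")
    rng = np.random.default_rng(spec.anchor_seed)
    idx = rng.choice(n, size=spec.n_anchor_points, replace=False)
    anchors = training.iloc[idx][["lon", "lat"]].to_numpy(dtype=float)
    if spec.n_anchor_points > 1 and np.allclose(anchors, anchors[0], atol=1e-12):
        raise ValueError("degenerate anchors: all anchor points coincide")

    tlon = training["lon"].to_numpy(dtype=float)
    tlat = training["lat"].to_numpy(dtype=float)
    d_train = np.column_stack([
        geo.distance_km(tlon, tlat, ax, ay, grid.crs) for ax, ay in anchors
    ])
    X, Y = grid.center_mesh()
    d_grid = np.column_stack([
        geo.distance_km(X.ravel(), Y.ravel(), ax, ay, grid.crs)
        for ax, ay in anchors
    ])

    if spec.n_anchor_points == 1:
        names = ["spatial1"]
        layers = {"spatial1": GeoGrid(d_grid[:, 0].reshape(X.shape), grid)}
        return SpatialFeatures(PredictorStack(layers), d_train, anchors, names)

    pca = PCA(n_components=spec.n_pca_components)
    train_scores = pca.fit_transform(d_train)
    grid_scores = pca.transform(d_grid)
    names = [f"spatial{i + 1}" for i in range(spec.n_pca_components)]
    layers = {
        name: GeoGrid(grid_scores[:, i].reshape(X.shape), grid)
        for i, name in enumerate(names)
    }
    return SpatialFeatures(PredictorStack(layers), train_scores, anchors, names)


def make_blocks(coords: np.ndarray, n_blocks: int, seed: int) -> np.ndarray:
    """Contiguous spatial blocks: k-means clusters of point coordinates.

    Blocks with fewer than two points are merged into the nearest block
    (by centroid distance) and the merge is logged.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    km = KMeans(n_clusters=n_blocks, random_state=seed, n_init=10)
    labels = km.fit_predict(coords)
    centers = km.cluster_centers_
    for b in range(n_blocks):
        if 0 < (labels == b).sum() < 2:
            d = np.linalg.norm(centers - centers[b], axis=1)
            d[b] = np.inf
            sizes = np.bincount(labels, minlength=n_blocks)
            d[sizes < 2] = np.inf
            target = int(np.argmin(d))
            log.info("merging singleton spatial block %d into block %d", b, target)
            labels[labels == b] = target
    return labels


def _oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    blocks: np.ndarray,
    learner_kinds: Sequence[str],
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Held-out predictions: each point predicted by learners fit without
    its spatial block.  Returns (n_points, n_learners) and the surviving
    learner names."""
    ss = np.random.SeedSequence(seed)
    learner_seeds = {k: int(s.generate_state(1)[0] % (2**31 - 1))
                     for k, s in zip(learner_kinds, ss.spawn(len(learner_kinds)))}
    oof = np.full((len(y), len(learner_kinds)), np.nan)
    failed: set[str] = set()
    for b in np.unique(blocks):
        hold = blocks == b
        for j, kind in enumerate(learner_kinds):
            if kind in failed:
                continue
            est = _make_learner(kind, learner_seeds[kind])
            try:
                est.fit(X[~hold], y[~hold])
                oof[hold, j] = est.predict(X[hold])
            except Exception as exc:  # noqa: BLE001 - any failure drops learner
                log.warning("learner %s failed (%s); dropping it", kind, exc)
                failed.add(kind)
    keep = [k for k in learner_kinds if k not in failed]
    cols = [j for j, k in enumerate(learner_kinds) if k not in failed]
    return oof[:, cols], keep


def _training_matrix(
    training: pd.DataFrame,
    stack: PredictorStack,
    selected: Sequence[str],
    spatial: SpatialFeatures | None,
) -> np.ndarray:
    Xp = extract_predictors(training, stack.subset(selected))
    if spatial is not None:
        return np.column_stack([Xp, spatial.train_values])
    return Xp


def fit_ensemble(
    training: pd.DataFrame,
    stack: PredictorStack,
    spec: SpatialFeatureSpec | None = SpatialFeatureSpec(),
    learners: Sequence[str] = DEFAULT_LEARNERS,
    selected: Sequence[str] | None = None,
    n_blocks: int = 5,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the stacked ensemble.

    Base learners are fit on the full data; the linear meta-learner is
    estimated by OLS of the observations on spatially blocked held-out
    base predictions, so the stacking weights are not contaminated by
    in-sample overfit.  Residuals stored on the model are leave-block-out
    meta residuals and feed the error model.
    """
    if len(set(learners)) < 2:
        raise ValueError("need at least two distinct learner kinds")
    for k in learners:
        if k not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {k!r}")
    if len(training) < 30:
        raise ValueError("need at least 30 training points")

    selected = list(selected) if selected is not None else stack.names
    spatial = (build_spatial_features(training, stack.spec, spec)
               if spec is not None else None)
    X = _training_matrix(training, stack, selected, spatial)
    y = training["ratio"].to_numpy(dtype=float)
    coords = training[["lon", "lat"]].to_numpy(dtype=float)
    blocks = make_blocks(coords, n_blocks, seed)

    oof, kept = _oof_predictions(X, y, blocks, list(learners), seed)
    if len(kept) < 2:
        raise RuntimeError("fewer than two base learners survived fitting")

    ols = sm.OLS(y, sm.add_constant(oof, has_constant="add")).fit()
    intercept = float(ols.params[0])
    weights = {k: float(w) for k, w in zip(kept, ols.params[1:])}
    tvalues = {k: float(t) for k, t in zip(kept, ols.tvalues[1:])}

    # stacked held-out predictions: base predictions are leave-block-out;
    # the meta's few coefficients (fit on all held-out columns) add
    # negligible optimism at these sample sizes
    meta_oof = ols.predict(sm.add_constant(oof, has_constant="add"))
    residuals = y - meta_oof
    rmse = float(np.sqrt(np.mean(residuals**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else float("nan")
    report = CvReport(rmse=rmse, r2=r2, fold_assignments=blocks)

    ss = np.random.SeedSequence(seed)
    learner_seeds = {k: int(s.generate_state(1)[0] % (2**31 - 1))
                     for k, s in zip(learners, ss.spawn(len(learners)))}
    fitted = {}
    for kind in kept:
        est = _make_learner(kind, learner_seeds[kind])
        est.fit(X, y)
        fitted[kind] = est

    return EnsembleModel(
        selected_predictors=selected, learners=fitted,
        meta_intercept=intercept, meta_weights=weights, meta_tvalues=tvalues,
        spatial=spatial, train_coords=coords, train_residuals=residuals,
        cv_report=report, crs=stack.spec.crs,
    )


def _grid_matrix(model: EnsembleModel, stack: PredictorStack) -> tuple[np.ndarray, np.ndarray]:
    missing = [n for n in model.selected_predictors if n not in stack.names]
    if missing:
        raise KeyError(f"predictor stack is missing selected layer(s): {missing}")
    sub = stack.subset(model.selected_predictors)
    spec = sub.spec
    cols = [sub[n].values.ravel() for n in model.selected_predictors]
    if model.spatial is not None:
        for name in model.spatial.names:
            cols.append(model.spatial.stack[name].values.ravel())
    X = np.column_stack(cols)
    valid = np.all(np.isfinite(X), axis=1)
    return X, valid.reshape(spec.nrows, spec.ncols)


def predict_isoscape(model: EnsembleModel, stack: PredictorStack) -> GeoGrid:
    """Per-pixel meta prediction; nodata wherever any predictor is nodata."""
    X, valid = _grid_matrix(model, stack)
    spec = stack.spec
    out = np.full(spec.nrows * spec.ncols, np.nan)
    v = valid.ravel()
    if v.any():
        out[v] = model.predict_matrix(X[v])
    return GeoGrid(out.reshape(spec.nrows, spec.ncols), spec)


def estimate_error(
    model: EnsembleModel,
    stack: PredictorStack,
    quantile_level: float = 0.67,
    intra_site_sd: float = 0.001,
    combine: str = "quadrature",
    k_neighbors: int = 30,
) -> ErrorModel:
    """Per-pixel prediction SD from a local held-out residual pool.

    For each pixel, the residuals of the ``k_neighbors`` nearest
    training points (held-out meta residuals from the blocked fit) are
    pooled; the SD is the half-width of their central
    ``quantile_level`` interval (for 0.67, ~1 Gaussian SD), combined
    with ``intra_site_sd`` in quadrature (default) or arithmetically.
    Neighbour search uses coordinate-space distance, adequate at the
    regional scales the grids cover.
    """
    if not 0.0 < quantile_level < 1.0:
        raise ValueError("quantile_level must be in (0, 1)")
    if intra_site_sd < 0:
        raise ValueError("intra_site_sd must be >= 0")
    if combine not in ("quadrature", "sum"):
        raise ValueError("combine must be 'quadrature' or 'sum'")
    spec = stack.spec
    tree = cKDTree(model.train_coords)
    X, Y = spec.center_mesh()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    k = min(k_neighbors, len(model.train_residuals))
    _, nbr = tree.query(pts, k=k)
    nbr = np.atleast_2d(nbr)
    if nbr.shape[0] != pts.shape[0]:
        nbr = nbr.reshape(pts.shape[0], -1)
    pool = model.train_residuals[nbr]
    lo = np.quantile(pool, 0.5 - quantile_level / 2, axis=1)
    hi = np.quantile(pool, 0.5 + quantile_level / 2, axis=1)
    half = (hi - lo) / 2.0
    # local residuals are not centred (spatial extrapolation bias); the
    # median offset is folded into the SD so the symmetric band stays
    # honest where the model is locally biased
    med = np.abs(np.median(pool, axis=1))
    if combine == "quadrature":
        sd = np.sqrt(half**2 + med**2 + intra_site_sd**2)
    else:
        sd = half + med + intra_site_sd
    _, valid = _grid_matrix(model, stack)
    sd = np.where(valid.ravel(), sd, np.nan)
    return ErrorModel(quantile_level=quantile_level, intra_site_sd=intra_site_sd,
                      sd_grid=GeoGrid(sd.reshape(spec.nrows, spec.ncols), spec))


def build_isoscape(model: EnsembleModel, stack: PredictorStack,
                   quantile_level: float = 0.67,
                   intra_site_sd: float = 0.001) -> Isoscape:
    """Convenience: mean prediction grid plus error-model SD grid."""
    mean = predict_isoscape(model, stack)
    err = estimate_error(model, stack, quantile_level=quantile_level,
                         intra_site_sd=intra_site_sd)
    return Isoscape(mean, err.sd_grid)


def spatial_cv(
    training: pd.DataFrame,
    stack: PredictorStack,
    spec: SpatialFeatureSpec | None = SpatialFeatureSpec(),
    learners: Sequence[str] = DEFAULT_LEARNERS,
    selected: Sequence[str] | None = None,
    n_blocks: int = 5,
    seed: int = 0,
) -> CvReport:
    """Spatially blocked cross-validation of the stacked ensemble.

    Points are partitioned into k-means blocks; every point is predicted
    by base learners fit without its block and a meta-learner fit on the
    remaining blocks' held-out predictions.  RMSE and R^2 are computed
    on the concatenated held-out predictions.
    """
    model = fit_ensemble(training, stack, spec=spec, learners=learners,
                         selected=selected, n_blocks=n_blocks, seed=seed)
    return model.cv_report


def single_learner_cv(
    training: pd.DataFrame,
    stack: PredictorStack,
    kind: str = "random_forest",
    spec: SpatialFeatureSpec | None = SpatialFeatureSpec(),
    selected: Sequence[str] | None = None,
    n_blocks: int = 5,
    seed: int = 0,
) -> CvReport:
    """Blocked CV of one base learner alone (the single-forest baseline)."""
    selected = list(selected) if selected is not None else stack.names
    spatial = (build_spatial_features(training, stack.spec, spec)
               if spec is not None else None)
    X = _training_matrix(training, stack, selected, spatial)
    y = training["ratio"].to_numpy(dtype=float)
    coords = training[["lon", "lat"]].to_numpy(dtype=float)
    blocks = make_blocks(coords, n_blocks, seed)
    oof, kept = _oof_predictions(X, y, blocks, [kind], seed)
    if not kept:
        raise RuntimeError(f"learner {kind} failed to fit")
    resid = y - oof[:, 0]
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return CvReport(rmse=rmse, r2=r2, fold_assignments=blocks)
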