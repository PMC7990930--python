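"""Step 1: droplet QC, cell/marker calling, and empirical profiles.

Droplets are gated by size (discarding broken-up or coalesced droplets),
classified as cell-containing via the cell-tracking-dye channel, and
each marker is called positive/negative from its probe channel by
unsupervised clustering of fluorescence intensities.  The stage emits
the observed droplet profile ``d`` (signature distribution among
cell-containing droplets), the ambient profile ``n`` (among empty
droplets), and the mean occupancy ``lambda`` estimated from the empty
fraction.

Three clustering methods are available per channel: a variational
Bayesian Gaussian mixture with a Dirichlet-process prior (the default;
no predefined cluster count), DBSCAN density clustering, and a fixed
intensity threshold.  Cluster polarity (positive/negative) is assigned
either automatically — clusters whose mean intensity exceeds the
lowest-mean cluster by a fold-change — or by an explicit user-supplied
map, which always takes precedence (mirroring manual cluster labeling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN
from sklearn.metrics import silhouette_score
from sklearn.mixture import BayesianGaussianMixture

from .signatures import MarkerPanel, SignatureProfile

__all__ = [
    "ClusteringSpec",
    "ClassifiedTable",
    "NoDropletsError",
    "filter_by_size",
    "cluster_channel",
    "assign_cluster_polarity",
    "build_classified_table",
    "DropletClassifier",
]

logger = logging.getLogger(__name__)

NOISE_LABEL = -1


class NoDropletsError(ValueError):
    """No droplets remain after QC, or a required class is empty."""


@dataclass(frozen=True)
class ClusteringSpec:
    """Configuration of one clustering pass over channel intensities.

    method : {"dpgmm", "dbscan", "threshold"}
        Dirichlet-process Gaussian mixture (default), density-based
        spatial clustering, or a fixed intensity threshold.
    label_map : optional {cluster id -> bool}
        Explicit positive/negative assignment; overrides the automatic
        fold-change policy when given.
    """

    method: str = "dpgmm"
    max_components: int = 10
    concentration: float | None = None     # DPGMM weight-concentration prior
    eps: float = 0.2                       # DBSCAN neighborhood radius (log10 units)
    min_samples: int = 10
    threshold: float | None = None
    log_transform: bool = True
    fold_change: float = 3.0               # automatic polarity policy
    label_map: Mapping[int, bool] | None = None
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("dpgmm", "dbscan", "threshold"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.method == "threshold" and self.threshold is None:
            raise ValueError("threshold method requires a threshold value")


def filter_by_size(
    table: pd.DataFrame,
    min_area: float = 0.0,
    max_area: float = math.inf,
    area_column: str = "area",
) -> pd.DataFrame:
    """Gate droplets on area; returns the passing rows.

    Droplets outside [min_area, max_area] (too small: broken up; too
    large: coalesced) are excluded from all downstream statistics, with
    the excluded counts logged.
    """
    if min_area >= max_area:
        raise ValueError(f"min_area ({min_area}) must be below max_area ({max_area})")
    if area_column not in table.columns:
        raise ValueError(f"area column {area_column!r} not present in table")
    area = table[area_column].to_numpy(dtype=float)
    too_small = area < min_area
    too_large = area > max_area
    keep = ~(too_small | too_large)
    logger.info("size gate [%g, %g]: %d pass, %d too small, %d too large",
                min_area, max_area, int(keep.sum()),
                int(too_small.sum()), int(too_large.sum()))
    if not keep.any():
        raise NoDropletsError("no droplets pass the size QC gate")
    return table.loc[keep].reset_index(drop=True)


def _prepare_values(values: np.ndarray, log_transform: bool) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")
    if log_transform:
        # fluorescence spans decades; a small offset keeps zeros finite
        x = np.log10(x + 1.0)
    return x


def cluster_channel(values, spec: ClusteringSpec | None = None) -> np.ndarray:
    """Cluster per-droplet intensities for one (or several) channels.

    Returns integer labels; DBSCAN may emit the noise label -1.  Labels
    of real clusters are relabeled by descending occupancy so that label
    0 is always the most populous cluster.  Degenerate (constant) input
    collapses to a single cluster with a logged warning.
    """
    spec = spec or ClusteringSpec()
    x = _prepare_values(values, spec.log_transform)
    n = x.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two droplets")

    if np.allclose(x, x[0], atol=1e-12):
        logger.warning("constant intensities: returning a single cluster")
        return np.zeros(n, dtype=int)

    if spec.method == "threshold":
        raw = np.asarray(values, dtype=float).reshape(n, -1)[:, 0]
        return (raw > spec.threshold).astype(int)

    if spec.method == "dbscan":
        labels = DBSCAN(eps=spec.eps, min_samples=spec.min_samples).fit_predict(x)
    else:  # dpgmm
        kwargs = {}
        if spec.concentration is not None:
            kwargs["weight_concentration_prior"] = spec.concentration
        gmm = BayesianGaussianMixture(
            n_components=min(spec.max_components, n),
            weight_concentration_prior_type="dirichlet_process",
            covariance_type="full",
            max_iter=500,
            random_state=spec.random_state,
            **kwargs,
        )
        labels = gmm.fit_predict(x)

    # compact labels, ordered by descending cluster size; keep noise at -1
    out = np.full(n, NOISE_LABEL, dtype=int)
    real = labels >= 0
    if real.any():
        uniq, counts = np.unique(labels[real], return_counts=True)
        order = uniq[np.argsort(-counts)]
        remap = {old: new for new, old in enumerate(order)}
        out[real] = [remap[v] for v in labels[real]]
    n_noise = int((~real).sum())
    if n_noise:
        logger.info("density clustering flagged %d droplets as noise", n_noise)
    return out


def assign_cluster_polarity(
    labels: np.ndarray,
    values,
    fold_change: float = 3.0,
    label_map: Mapping[int, bool] | None = None,
    geometric: bool = True,
    min_anchor_fraction: float = 0.01,
) -> np.ndarray:
    """Boolean positive/negative call per droplet from cluster labels.

    Automatic policy: the lowest-center cluster anchors the negative
    population; any cluster whose center exceeds the anchor by
    ``fold_change`` is positive.  With ``geometric`` (the default)
    cluster centers are geometric means, which is robust to the
    mixture splitting a log-normal mode into sub-clusters whose
    arithmetic means differ by tail weight alone; clusters holding
    fewer than ``min_anchor_fraction`` of the droplets cannot serve as
    the anchor (a handful of low outliers must not drag it down).  An
    explicit ``label_map`` (mirroring manual labeling) is applied
    verbatim and must cover every non-noise cluster.  Noise droplets
    are called negative here; callers that need to exclude them should
    mask on ``labels == -1``.
    """
    labels = np.asarray(labels)
    raw = np.asarray(values, dtype=float).reshape(labels.size, -1)[:, 0]
    ids = [int(c) for c in np.unique(labels) if c != NOISE_LABEL]

    if label_map is not None:
        missing = [c for c in ids if c not in label_map]
        if missing:
            raise ValueError(f"label map is missing cluster ids: {missing}")
        polarity = {c: bool(label_map[c]) for c in ids}
    else:
        if geometric:
            center = lambda x: float(np.exp(np.mean(np.log(x + 1.0)))) - 1.0
        else:
            center = lambda x: float(x.mean())
        means = {c: center(raw[labels == c]) for c in ids}
        if len(ids) == 1:
            logger.warning("single cluster found: calling all droplets negative "
                           "(no amplification detected)")
            polarity = {ids[0]: False}
        else:
            sizes = {c: int((labels == c).sum()) for c in ids}
            min_size = max(1, int(min_anchor_fraction * labels.size))
            anchors = [means[c] for c in ids if sizes[c] >= min_size] or list(means.values())
            low = min(anchors)
            # guard against a zero-intensity negative cluster
            floor = low if low > 0 else max(means.values()) / (10 * fold_change)
            polarity = {c: means[c] > fold_change * floor for c in ids}
    calls = np.zeros(labels.size, dtype=bool)
    for c, pos in polarity.items():
        if pos:
            calls[labels == c] = True
    return calls


@dataclass
class ClassifiedTable:
    """Output of Step 1: per-droplet calls plus the empirical profiles.

    d and n are the signature distributions over cell-containing and
    empty droplets respectively; lambda_ = -ln(empty fraction) among
    QC-pass, non-noise droplets.
    """

    table: pd.DataFrame
    panel: MarkerPanel
    d: SignatureProfile
    n: SignatureProfile
    lambda_: float
    empty_fraction: float
    counts: dict = field(default_factory=dict)
    separation: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "d": list(map(float, self.d.values)),
            "n": list(map(float, self.n.values)),
            "lambda": self.lambda_,
            "empty_fraction": self.empty_fraction,
            "counts": self.counts,
            "separation": self.separation,
        }


def _separation_score(x: np.ndarray, calls: np.ndarray) -> float:
    """Silhouette-style diagnostic of positive/negative separation."""
    if calls.all() or not calls.any() or x.size < 3:
        return float("nan")
    try:
        return float(silhouette_score(x.reshape(-1, 1), calls.astype(int)))
    except ValueError:  # pragma: no cover - degenerate tiny inputs
        return float("nan")


def build_classified_table(
    table: pd.DataFrame,
    panel: MarkerPanel,
    specs: Mapping[str, ClusteringSpec] | None = None,
    default_spec: ClusteringSpec | None = None,
) -> ClassifiedTable:
    """Call cells and markers for every droplet and build d, n and lambda.

    ``table`` must carry one intensity column per panel channel (already
    size-gated).  ``specs`` may override the clustering spec per channel
    name; ``default_spec`` applies elsewhere.
    """
    specs = dict(specs or {})
    default_spec = default_spec or ClusteringSpec()
    channels = [panel.cell_channel] + panel.marker_channels()
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing channel columns: {missing}")
    if len(table) < 2:
        raise NoDropletsError("need at least two droplets to classify")

    calls: dict[str, np.ndarray] = {}
    noise = np.zeros(len(table), dtype=bool)
    separation: dict[str, float] = {}
    for ch in channels:
        spec = specs.get(ch, default_spec)
        vals = table[ch].to_numpy(dtype=float)
        labels = cluster_channel(vals, spec)
        calls[ch] = assign_cluster_polarity(labels, vals, spec.fold_change,
                                            spec.label_map, geometric=spec.log_transform)
        noise |= labels == NOISE_LABEL
        prepared = _prepare_values(vals, spec.log_transform)[:, 0]
        separation[ch] = _separation_score(prepared, calls[ch])

    n_noise = int(noise.sum())
    if n_noise:
        logger.info("excluding %d noise-labeled droplets from d/n", n_noise)
    keep = ~noise

    has_cell = calls[panel.cell_channel]
    marker_calls = np.column_stack([calls[c] for c in panel.marker_channels()])
    # marker 1 = least-significant bit of the signature index
    weights = 1 << np.arange(panel.n_markers)
    sig_index = marker_calls @ weights + 1

    out = table.copy()
    out["has_cell"] = has_cell
    for i, name in enumerate(panel.markers):
        out[f"call_{name}"] = marker_calls[:, i]
    out["signature_index"] = sig_index
    out["noise"] = noise

    cell_mask = keep & has_cell
    empty_mask = keep & ~has_cell
    n_pass = int(keep.sum())
    n_cells = int(cell_mask.sum())
    n_empty = int(empty_mask.sum())
    if n_empty == 0:
        raise NoDropletsError(
            "no empty droplets: lambda cannot be estimated; dilute the sample"
        )
    if n_cells == 0:
        raise NoDropletsError("no cell-containing droplets: droplet profile d is undefined")

    g = panel.n_signatures
    d_counts = np.bincount(sig_index[cell_mask] - 1, minlength=g)
    n_counts = np.bincount(sig_index[empty_mask] - 1, minlength=g)
    empty_fraction = n_empty / n_pass
    lam = -math.log(empty_fraction)

    return ClassifiedTable(
        table=out,
        panel=panel,
        d=SignatureProfile.from_counts(d_counts, role="droplet"),
        n=SignatureProfile.from_counts(n_counts, role="ambient"),
        lambda_=lam,
        empty_fraction=empty_fraction,
        counts={
            "pass": n_pass,
            "noise": n_noise,
            "cell": n_cells,
            "empty": n_empty,
        },
        separation=separation,
    )


class DropletClassifier(BaseEstimator):
    """Step-1 estimator over a droplet measurement table.

    ``fit`` gates droplets by area, clusters each configured channel and
    derives the empirical profiles; ``transform`` returns the per-droplet
    call table.  The per-table outputs live in the fitted attributes
    ``d_``, ``n_``, ``lambda_``, ``empty_fraction_`` and ``counts_``.
    """

    def __init__(self, panel: MarkerPanel | None = None,
                 min_area: float = 0.0, max_area: float = math.inf,
                 area_column: str = "area",
                 specs: Mapping[str, ClusteringSpec] | None = None,
                 default_spec: ClusteringSpec | None = None):
        self.panel = panel
        self.min_area = min_area
        self.max_area = max_area
        self.area_column = area_column
        self.specs = specs
        self.default_spec = default_spec

    def fit(self, X: pd.DataFrame, y=None):
        panel = self.panel
        if panel is None:
            raise ValueError("a MarkerPanel is required")
        gated = filter_by_size(X, self.min_area, self.max_area, self.area_column)
        result = build_classified_table(gated, panel, self.specs, self.default_spec)
        self.result_ = result
        self.d_ = result.d
        self.n_ = result.n
        self.lambda_ = result.lambda_
        self.empty_fraction_ = result.empty_fraction
        self.counts_ = result.counts
        self.separation_ = result.separation
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise ValueError("classifier is not fitted")
        return self.result_.table

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform()
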