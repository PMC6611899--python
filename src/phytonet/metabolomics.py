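"""Two-group metabolomics: preprocessing, PCA, PLS-DA (NIPALS) and VIP.

The discriminant workflow mirrors the SIMCA-style analysis of a
two-group plasma-metabolite table: impute, log, centre/scale; inspect a
PCA; fit a PLS-DA model with a dummy-coded response; rank metabolites by
variable importance in projection (VIP); and call differential
metabolites with a dual criterion (VIP above threshold AND a BH-adjusted
two-sided rank-sum test below alpha).  PLS-DA stands in for OPLS-DA: with
two groups the predictive subspace is identical, the orthogonal split
being a display convenience.

Conventions fixed for determinism: variance uses the n-1 denominator
everywhere; PCA/PLS component signs are chosen so the largest-magnitude
loading (weight) is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Samples x metabolites intensity matrix with per-sample group labels."""

    intensities: pd.DataFrame  # index: sample ids, columns: metabolite ids
    groups: pd.Series  # aligned to intensities.index

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.intensities.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.intensities.shape[1]

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    @classmethod
    def from_tsv(cls, path, group_column: str = "group") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if group_column not in df.columns:
            raise ValueError(f"feature table needs a {group_column!r} column")
        groups = df[group_column].astype(str)
        return cls(intensities=df.drop(columns=[group_column]).astype(float), groups=groups)

    def to_tsv(self, path, group_column: str = "group") -> None:
        out = self.intensities.copy()
        out.insert(0, group_column, self.groups)
        out.to_csv(path, sep="\t")


@dataclass
class LatentModel:
    """Fitted latent-variable model (PCA or PLS-DA)."""

    kind: str  # "pca" | "plsda"
    scores: np.ndarray  # samples x components (T)
    loadings: np.ndarray  # metabolites x components (P)
    weights: np.ndarray | None  # metabolites x components (W, PLS only)
    explained: np.ndarray  # fraction of X-variance per component
    sample_ids: list[str]
    feature_ids: list[str]
    y_loadings: np.ndarray | None = None  # q per component (PLS only)
    ssy: np.ndarray | None = None  # explained response SS per component
    group_codes: pd.Series | None = None
    vip_: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def preprocess(
    table: FeatureTable,
    log_transform: bool = True,
    scaling: str = "unit_variance",
) -> FeatureTable:
    """Impute, optionally log-transform, mean-centre and scale.

    Missing cells are imputed with half the metabolite's observed minimum
    (the usual below-detection-limit convention).  Scaling is
    ``unit_variance`` (autoscaling, n-1), ``pareto`` (sqrt of sd) or
    ``none`` (centring only).  Zero-variance metabolites are dropped with
    a warning under unit_variance/pareto.
    """
    if scaling not in ("unit_variance", "pareto", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    x = table.intensities.copy()
    if x.empty:
        raise ValueError("empty feature table")
    all_missing = x.columns[x.isna().all()]
    if len(all_missing):
        logger.warning("dropping %d all-missing metabolite(s)", len(all_missing))
        x = x.drop(columns=all_missing)
    if x.isna().any().any():
        x = x.fillna(x.min() / 2.0)
    if log_transform:
        if (x <= 0).any().any():
            raise ValueError("log transform requires strictly positive intensities")
        x = np.log(x)
    x = x - x.mean()
    if scaling != "none":
        sd = x.std(ddof=1)
        degenerate = sd.index[(sd == 0) | sd.isna()]
        if len(degenerate):
            logger.warning(
                "dropping %d zero-variance metabolite(s) under %s scaling",
                len(degenerate),
                scaling,
            )
            x = x.drop(columns=degenerate)
            sd = sd.drop(degenerate)
        x = x / (sd if scaling == "unit_variance" else np.sqrt(sd))
    return FeatureTable(intensities=x, groups=table.groups.copy())


def _fix_signs(vectors: np.ndarray, companions: list[np.ndarray]) -> None:
    """Flip each column so its largest-magnitude entry is positive (in place)."""
    for a in range(vectors.shape[1]):
        col = vectors[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, a] = -col
            for other in companions:
                other[:, a] = -other[:, a]


def pca(table: FeatureTable, n_components: int = 2) -> LatentModel:
    """Principal components via SVD of the (already centred) matrix."""
    x = table.intensities.to_numpy(dtype=float)
    x = x - x.mean(axis=0)  # idempotent on preprocessed input
    rank = int(np.linalg.matrix_rank(x))
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncating", n_components, rank)
        n_components = rank
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[:n_components].T.copy()
    _fix_signs(loadings, [])
    scores = x @ loadings  # T = X P under the fixed sign convention
    total_var = np.sum(s**2)
    explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return LatentModel(
        kind="pca",
        scores=scores,
        loadings=loadings,
        weights=None,
        explained=explained,
        sample_ids=list(table.intensities.index),
        feature_ids=list(table.intensities.columns),
    )


def encode_groups(groups: pd.Series) -> pd.Series:
    """Dummy-code a two-level group factor as -1/+1 (lexicographic order)."""
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"discriminant analysis needs exactly 2 groups, got {levels}")
    return groups.map({levels[0]: -1.0, levels[1]: 1.0}).astype(float)


def plsda(
    table: FeatureTable,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> LatentModel:
    """PLS-DA by NIPALS with a single -1/+1 response column.

    Per component: iterate w = X'u / ||X'u||, t = X w, q = y't / t't,
    u = y q until the score change falls below ``tol`` (or ``max_iter``);
    then deflate X by t p' and y by t q.  With a univariate response the
    loop converges in one pass, but the general iteration is kept.
    """
    y_series = encode_groups(table.groups)
    x = table.intensities.to_numpy(dtype=float).copy()
    y = y_series.to_numpy(dtype=float).copy()
    y = y - y.mean()
    n, p = x.shape
    n_components = min(n_components, p, n - 1)
    total_ssx = np.sum(x**2)
    total_ssy = np.sum(y**2)
    if total_ssy == 0:
        raise ValueError("response has no variance")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    explained = np.zeros(n_components)
    for a in range(n_components):
        u = y.copy()
        t = np.zeros(n)
        for _ in range(max_iter):
            w = x.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: X'u vanished")
            w /= norm
            t_new = x @ w
            q = float(y @ t_new) / float(t_new @ t_new)
            u = y * q
            if np.linalg.norm(t_new - t) < tol:
                t = t_new
                break
            t = t_new
        tt = float(t @ t)
        p_vec = x.T @ t / tt
        q = float(y @ t) / tt
        x = x - np.outer(t, p_vec)
        y = y - t * q
        W[:, a], P[:, a], T[:, a], Q[a] = w, p_vec, t, q
        ssy[a] = q * q * tt
        explained[a] = np.sum((np.outer(t, p_vec)) ** 2) / total_ssx if total_ssx else 0.0

    _fix_signs(W, [P, T, Q.reshape(1, -1)])
    model = LatentModel(
        kind="plsda",
        scores=T,
        loadings=P,
        weights=W,
        explained=explained,
        sample_ids=list(table.intensities.index),
        feature_ids=list(table.intensities.columns),
        y_loadings=Q,
        ssy=ssy,
        group_codes=y_series,
    )
    model.vip_ = vip(model)
    return model


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection for a fitted PLS model.

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a ),
    so the mean squared VIP over the p metabolites is exactly 1.
    """
    if model.kind != "plsda" or model.weights is None or model.ssy is None:
        raise ValueError("VIP requires a fitted PLS-DA model")
    ssy = model.ssy
    if np.sum(ssy) <= 0:
        raise ValueError("model explains no response variance")
    w = model.weights
    w_norm2 = np.sum(w**2, axis=0)
    w_norm2[w_norm2 == 0] = 1.0
    contrib = (w**2 / w_norm2) @ ssy
    p = w.shape[0]
    return np.sqrt(p * contrib / np.sum(ssy))


def separation_statistic(model: LatentModel) -> float:
    """Fraction of response variance captured (R2Y) — a separation gauge."""
    if model.ssy is None or model.group_codes is None:
        raise ValueError("needs a fitted PLS-DA model")
    y = model.group_codes.to_numpy(dtype=float)
    y = y - y.mean()
    return float(np.sum(model.ssy) / np.sum(y**2))


def select_differential(
    table: FeatureTable,
    model: LatentModel,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Differential metabolites: VIP > threshold AND BH-q < alpha.

    The two-sided test (Wilcoxon rank-sum by default, Welch t via
    ``test="t"``) runs on the *raw* table intensities; direction is the
    sign of the treatment-minus-control mean difference, where "treatment"
    is the group dummy-coded +1 (lexicographically second).  Output is
    ordered by VIP descending.
    """
    if model.vip_ is None:
        raise ValueError("model has no VIP scores")
    levels = table.group_levels
    if len(levels) != 2:
        raise ValueError("differential selection needs exactly 2 groups")
    control, treatment = levels
    vips = pd.Series(model.vip_, index=model.feature_ids)
    raw = table.intensities[model.feature_ids]
    a = raw[table.groups == treatment]
    b = raw[table.groups == control]
    pvals = np.ones(raw.shape[1])
    for j, met in enumerate(raw.columns):
        x1, x0 = a[met].dropna(), b[met].dropna()
        if x1.nunique() <= 1 and x0.nunique() <= 1 and x1.iloc[0] == x0.iloc[0]:
            continue  # identical constants: no evidence
        if test == "ranksum":
            pvals[j] = stats.mannwhitneyu(x1, x0, alternative="two-sided").pvalue
        elif test == "t":
            pvals[j] = stats.ttest_ind(x1, x0, equal_var=False).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    qvals = bh_fdr(pvals)
    diff_mean = a.mean() - b.mean()
    out = pd.DataFrame(
        {
            "metabolite": raw.columns,
            "vip": vips.values,
            "p": pvals,
            "q": qvals,
            "direction": np.where(diff_mean.values >= 0, "increased", "decreased"),
        }
    )
    out = out[(out["vip"] > vip_threshold) & (out["q"] < alpha)]
    return out.sort_values(["vip", "metabolite"], ascending=[False, True], ignore_index=True)


def heatmap_matrix(
    table: FeatureTable, selected: list[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Z-score matrix (metabolites x samples) with clustered row order.

    Rows (metabolites) are ordered by average-linkage hierarchical
    clustering on Euclidean distance of the z-score profiles; columns are
    grouped by label then sample id.  Zero-variance metabolites get z = 0
    with a warning.  Returns (matrix, row_order, column_order).
    """
    if not selected:
        raise ValueError("need at least one selected metabolite")
    x = table.intensities[list(selected)]
    sd = x.std(ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var):
        logger.warning("%d zero-variance metabolite(s): z set to 0", len(zero_var))
    z = (x - x.mean()) / sd.replace(0, np.nan)
    z = z.fillna(0.0)
    zmat = z.T  # metabolites in rows
    if zmat.shape[0] > 2:
        link = average(pdist(zmat.to_numpy(), metric="euclidean"))
        row_order = [zmat.index[i] for i in leaves_list(link)]
    else:
        row_order = list(zmat.index)
    col_order = sorted(zmat.columns, key=lambda s: (str(table.groups.loc[s]), str(s)))
    ordered = zmat.loc[row_order, col_order]
    return ordered, row_order, col_order
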