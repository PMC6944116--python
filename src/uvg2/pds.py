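"""Pathway deregulation scores from a principal curve, implemented from scratch.

A pathway's per-sample deregulation score (PDS) is the normalized arc-length
position of the sample along a one-dimensional principal curve threaded
through the cloud of pathway-restricted expression profiles: 0 means
reference-like, 1 maximally deregulated. The construction follows the
Pathifier recipe — standardize genes, reduce by PCA to the components
covering a set fraction of variance (at least two), fit a Hastie–Stuetzle
principal curve, and read each sample's score off the curve after orienting
it so that designated reference samples sit at the low end.

The curve fit alternates projection of the points onto the current polyline
with scatterplot smoothing of each coordinate against arc length. The
smoother is a local linear regression over a rank-window of the samples
(span a fixed fraction of the cohort); local linear fits reproduce affine
coordinate functions exactly, so for collinear data the fitted curve is the
first principal-component segment and the PDS reduces in closed form to the
normalized first-PC projection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "reduce_expression",
    "PrincipalCurve",
    "PathwayDeregulationScore",
    "single_gene_pds",
]


def reduce_expression(
    expr: pd.DataFrame, var_fraction: float = 0.9, min_genes: int = 3
):
    """Standardize genes and project samples onto leading principal components.

    ``expr`` is samples x genes. Genes are z-scored across samples;
    zero-variance genes are dropped with a warning. Components are retained
    up to cumulative explained variance >= ``var_fraction`` with a floor of
    two. Returns ``(scores, pca, genes_used, mean, scale)``.
    """
    if expr.shape[0] < 10:
        raise ValueError(f"need >= 10 samples, got {expr.shape[0]}")
    mean = expr.mean(axis=0)
    scale = expr.std(axis=0, ddof=1)
    usable = scale > 0
    if (~usable).any():
        warnings.warn(
            f"dropping {int((~usable).sum())} zero-variance gene(s): "
            f"{list(expr.columns[~usable])[:5]}"
        )
    genes_used = list(expr.columns[usable])
    if len(genes_used) < min_genes:
        raise ValueError(f"fewer than {min_genes} usable genes")
    z = (expr[genes_used] - mean[genes_used]) / scale[genes_used]
    n_max = min(z.shape[0] - 1, len(genes_used))
    pca = PCA(n_components=n_max, svd_solver="full")
    all_scores = pca.fit_transform(z.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_fraction) + 1)
    k = max(2, min(k, n_max))
    return all_scores[:, :k], pca, genes_used, mean[genes_used], scale[genes_used]


def _local_linear_smooth(lam: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local linear regression of each column of y on lam, rank-windowed.

    ``lam`` must be sorted ascending. The window around sample i covers
    ``h`` neighbours on each side with h = max(2, ceil(span*n/2)), clipped
    at the boundaries (asymmetric windows near the ends). Affine functions
    of lam are reproduced exactly.
    """
    n = len(lam)
    h = max(2, int(np.ceil(span * n / 2.0)))
    out = np.empty_like(y, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        lw = lam[lo:hi]
        yw = y[lo:hi]
        lbar = lw.mean()
        dl = lw - lbar
        denom = float(dl @ dl)
        ybar = yw.mean(axis=0)
        if denom <= 1e-300:
            out[i] = ybar
        else:
            slope = (dl @ yw) / denom
            out[i] = ybar + slope * (lam[i] - lbar)
    return out


def _project_to_polyline(X: np.ndarray, P: np.ndarray):
    """Project points X (n,k) onto the polyline through P (m,k).

    Returns (lam, dist2): arc-length positions along the polyline and
    squared distances. Zero-length segments are handled as points.
    """
    seg_vec = P[1:] - P[:-1]  # (m-1, k)
    seg_len2 = (seg_vec**2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if len(P) == 1 or cum[-1] == 0.0:
        d2 = ((X - P[0]) ** 2).sum(axis=1)
        return np.zeros(len(X)), d2
    # foot-of-perpendicular parameter per (point, segment), clipped to [0,1];
    # everything is expressed through matrix products to avoid an n*m*k array
    A = P[:-1]
    Xd = X @ seg_vec.T  # (n, m-1)
    Ad = (A * seg_vec).sum(axis=1)  # (m-1,)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = (Xd - Ad[None, :]) / seg_len2[None, :]
    tt = np.where(seg_len2[None, :] > 0, np.clip(tt, 0.0, 1.0), 0.0)
    # ||X - a - t d||^2 = ||X - a||^2 - 2 t (X-a).d + t^2 ||d||^2
    xa2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * (X @ A.T)
        + (A**2).sum(axis=1)[None, :]
    )
    xad = Xd - Ad[None, :]
    d2 = xa2 - 2.0 * tt * xad + tt**2 * seg_len2[None, :]
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(X))
    lam = cum[best] + tt[idx, best] * seg_len[best]
    return lam, np.maximum(d2[idx, best], 0.0)


class PrincipalCurve(BaseEstimator):
    """Hastie–Stuetzle principal curve through a point cloud.

    Parameters
    ----------
    tol : float
        Relative change in mean squared projection distance below which the
        alternation stops.
    max_iter : int
        Iteration cap; non-convergence is reported via ``converged_``.
    span : float
        Fraction of the samples in each local-linear smoothing window.

    Attributes (after ``fit``)
    --------------------------
    points_ : ndarray, ordered curve points (discretized at the projected
        sample positions).
    lambda_ : ndarray, per-sample arc-length position in [0, length_].
    length_ : float, total curve length.
    converged_ : bool; n_iter_ : int.
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 50, span: float = 0.3):
        self.tol = tol
        self.max_iter = max_iter
        self.span = span

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if n < 10:
            raise ValueError(f"need >= 10 points to fit a curve, got {n}")
        center = X.mean(axis=0)
        Xc = X - center
        if np.allclose(Xc, 0.0):
            # degenerate cloud: zero-length curve at the common point
            self.points_ = X[:1].copy()
            self.lambda_ = np.zeros(n)
            self.length_ = 0.0
            self.converged_ = True
            self.n_iter_ = 0
            return self
        # initialize along the first principal component
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        lam = Xc @ vt[0]
        order = np.argsort(lam, kind="stable")
        P = center + np.outer(lam[order], vt[0])
        lam, d2 = _project_to_polyline(X, P)
        mse = float(d2.mean())
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            order = np.argsort(lam, kind="stable")
            lam_ord = lam[order]
            P = _local_linear_smooth(lam_ord, X[order], self.span)
            lam, d2 = _project_to_polyline(X, P)
            new_mse = float(d2.mean())
            denom = mse if mse > 0 else 1.0
            if abs(mse - new_mse) < self.tol * denom:
                mse = new_mse
                self.converged_ = True
                break
            mse = new_mse
        self.points_ = P
        self.lambda_ = lam
        self.length_ = float(
            np.sqrt(((P[1:] - P[:-1]) ** 2).sum(axis=1)).sum()
        )
        self.mse_ = mse
        self.n_iter_ = it
        return self

    def project(self, X):
        """Arc-length positions of new points on the fitted curve."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        lam, _ = _project_to_polyline(X, self.points_)
        return lam


def orient_and_scale(
    lam: np.ndarray, length: float, ref_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Normalize arc length to [0,1], flipping so references sit low.

    Returns (pds, orientation) with orientation +1 (kept) or -1 (flipped).
    A zero-length curve yields all-zero scores.
    """
    if length <= 0:
        return np.zeros_like(lam, dtype=float), 1
    if not ref_mask.any():
        raise ValueError(
            "empty reference set: designate reference (baseline) samples"
        )
    pds = lam / length
    orientation = 1
    if np.median(pds[ref_mask]) > 0.5:
        pds = 1.0 - pds
        orientation = -1
    return np.clip(pds, 0.0, 1.0), orientation


class PathwayDeregulationScore(BaseEstimator, TransformerMixin):
    """Per-sample pathway deregulation score via a principal curve.

    ``fit`` takes a samples x genes expression DataFrame restricted to one
    pathway plus the ids (or boolean mask) of reference samples; ``transform``
    returns scores in [0, 1] for the fitted cohort or for new samples
    projected onto the frozen curve.

    Parameters
    ----------
    var_fraction : float
        Cumulative explained-variance target for the PCA reduction
        (>= 2 components always kept).
    tol, max_iter, span : principal-curve settings (see PrincipalCurve).
    min_genes : int
        Minimum usable (non-constant) genes.
    """

    def __init__(
        self,
        var_fraction: float = 0.9,
        tol: float = 1e-4,
        max_iter: int = 50,
        span: float = 0.3,
        min_genes: int = 3,
    ):
        self.var_fraction = var_fraction
        self.tol = tol
        self.max_iter = max_iter
        self.span = span
        self.min_genes = min_genes

    def fit(self, X: pd.DataFrame, y=None, reference=None):
        if reference is None:
            raise ValueError(
                "empty reference set: designate reference (baseline) samples "
                "via fit(..., reference=[ids])"
            )
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        scores, pca, genes_used, mean, scale = reduce_expression(
            X, self.var_fraction, self.min_genes
        )
        ref_mask = self._reference_mask(X.index, reference)
        curve = PrincipalCurve(tol=self.tol, max_iter=self.max_iter, span=self.span)
        curve.fit(scores)
        pds, orientation = orient_and_scale(curve.lambda_, curve.length_, ref_mask)
        self.genes_used_ = genes_used
        self.mean_ = mean
        self.scale_ = scale
        self.pca_ = pca
        self.n_components_ = scores.shape[1]
        self.curve_ = curve
        self.orientation_ = orientation
        self.reference_ids_ = list(np.asarray(X.index)[ref_mask])
        self.pds_ = pd.Series(pds, index=X.index, name="pds")
        return self

    @staticmethod
    def _reference_mask(index, reference) -> np.ndarray:
        ref = np.asarray(reference)
        if ref.dtype == bool:
            mask = ref
        else:
            mask = np.asarray(pd.Index(index).isin(ref))
        if mask.sum() == 0:
            raise ValueError(
                "empty reference set: designate reference (baseline) samples"
            )
        return mask

    def transform(self, X) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.genes_used_)
        z = (X[self.genes_used_] - self.mean_) / self.scale_
        pts = self.pca_.transform(z.to_numpy())[:, : self.n_components_]
        lam = self.curve_.project(pts)
        if self.curve_.length_ <= 0:
            return np.zeros(len(X))
        pds = lam / self.curve_.length_
        if self.orientation_ < 0:
            pds = 1.0 - pds
        return np.clip(pds, 0.0, 1.0)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).pds_.to_numpy()


def single_gene_pds(values: pd.Series, reference_ids) -> pd.Series:
    """One-dimensional deregulation score for a single gene.

    Min–max-normalized expression, flipped so the reference samples' median
    sits at the low end. A constant gene yields all-zero scores with a
    warning.
    """
    x = values.astype(float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(f"gene {values.name!r} is constant; PDS set to 0")
        return pd.Series(0.0, index=x.index, name=values.name)
    ref_mask = PathwayDeregulationScore._reference_mask(x.index, reference_ids)
    pds = (x - lo) / (hi - lo)
    if np.median(pds.to_numpy()[ref_mask]) > 0.5:
        pds = 1.0 - pds
    return pds.rename(values.name)
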