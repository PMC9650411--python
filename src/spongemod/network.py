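"""Signed weighted co-expression network construction and module detection.

The network pipeline follows the standard signed-WGCNA recipe: Pearson
correlation mapped to [0, 1] by the signed linear transform s = (1 + r) / 2,
soft thresholding a = s^beta with beta chosen by scale-free topology fit,
topological overlap, average-linkage clustering of 1 - TOM, a static-height
tree cut with a minimum module size, and SVD module eigengenes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkError",
    "ModuleAssignment",
    "EigengeneMatrix",
    "SoftThresholdResult",
    "signed_similarity",
    "adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "cut_modules",
    "module_eigengene",
    "module_trait_correlation",
]


class NetworkError(ValueError):
    pass


def _check_square(m: pd.DataFrame, name: str) -> None:
    vals = m.to_numpy()
    if vals.shape[0] != vals.shape[1]:
        raise NetworkError(f"{name} must be square")
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise NetworkError(f"{name} must be symmetric")
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise NetworkError(f"{name} entries must lie in [0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 marks unassigned (background) genes."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in set(self.labels) if m != 0)

    @property
    def sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels != 0].value_counts()
        return {int(m): int(c) for m, c in counts.items()}

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


@dataclass
class EigengeneMatrix:
    """Module eigengenes (modules x samples) and variance explained."""

    values: pd.DataFrame
    var_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class SoftThresholdResult:
    power: int
    fits: dict[int, float]
    warning: bool = False


# ---------------------------------------------------------------------------
# similarity / adjacency


def signed_similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """Signed similarity s_ij = (1 + pearson(x_i, x_j)) / 2 over gene rows."""
    vals = expr.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise NetworkError("need at least 3 samples")
    sds = vals.std(axis=1)
    if (sds == 0).any():
        gene = expr.index[int(np.argmax(sds == 0))]
        raise NetworkError(f"gene {gene!r} has zero variance")
    r = np.corrcoef(vals)
    s = (1.0 + r) / 2.0
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=expr.index, columns=expr.index)


def adjacency(similarity: pd.DataFrame, power: int) -> pd.DataFrame:
    """Soft-thresholded adjacency a_ij = s_ij ** power."""
    _check_square(similarity, "similarity")
    if power < 1:
        raise NetworkError("power must be >= 1")
    return similarity.pow(power)


# ---------------------------------------------------------------------------
# scale-free topology fit


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the binned log-log connectivity distribution fit."""
    if np.unique(k).size < 2:
        raise NetworkError("all connectivities identical; scale-free fit undefined")
    counts, edges = np.histogram(k, bins=n_bins)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / k.size
    usable = mean_k > 0
    if usable.sum() < 2:
        raise NetworkError("fewer than 2 usable connectivity bins")
    fit = stats.linregress(np.log10(mean_k[usable]), np.log10(freq[usable]))
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed scale-free topology R^2 of an adjacency matrix.

    Connectivity k_i is the off-diagonal row sum. Frequencies of binned k are
    regressed on mean k per bin on log10 scales; the squared correlation is
    returned with the sign flipped when frequency *increases* with k (a
    scale-free network must have a decreasing log-log relationship).
    """
    _check_square(adj, "adjacency")
    vals = adj.to_numpy()
    k = vals.sum(axis=1) - np.diag(vals)
    return _scale_free_r2(k, n_bins)


def pick_soft_threshold(
    similarity: pd.DataFrame,
    powers: list[int] | None = None,
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Smallest power whose signed scale-free R^2 reaches ``r2_cutoff``.

    Falls back (with ``warning=True``) to the power with maximal R^2 if no
    candidate reaches the cutoff.
    """
    powers = list(range(1, 21)) if powers is None else sorted(powers)
    if not powers:
        raise NetworkError("no candidate powers")
    fits: dict[int, float] = {}
    for p in powers:
        fits[p] = scale_free_fit(adjacency(similarity, p), n_bins)
        if fits[p] >= r2_cutoff:
            return SoftThresholdResult(power=p, fits=fits)
    best = max(fits, key=lambda p: fits[p])
    warnings.warn(
        f"no candidate power reached scale-free R^2 {r2_cutoff}; "
        f"using argmax power {best} (R^2 = {fits[best]:.3f})"
    )
    return SoftThresholdResult(power=best, fits=fits, warning=True)


# ---------------------------------------------------------------------------
# topological overlap


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix of a soft-thresholded adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and k the off-diagonal connectivity; TOM_ii = 1.
    """
    _check_square(adj, "adjacency")
    a = adj.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # (shared)_ij = sum_u a_iu a_uj over u != i, j given zero diag
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection


def cut_modules(
    tom: pd.DataFrame,
    min_module_size: int = 50,
    cut_fraction: float = 0.99,
) -> ModuleAssignment:
    """Static-height tree cut of the average-linkage 1 - TOM dendrogram.

    The dendrogram is cut at ``cut_fraction`` times its maximum merge height
    (the static-cut convention: in a TOM dendrogram the uncorrelated bulk
    merges in a narrow band just below the top, so a cut slightly under the
    top join isolates the tight module branches). Connected subtrees below
    the cut become candidate modules; those smaller than ``min_module_size``
    are set to label 0. Labels are renumbered 1..K by decreasing size.
    """
    _check_square(tom, "TOM")
    genes = tom.index
    if len(genes) < min_module_size:
        return ModuleAssignment(pd.Series(0, index=genes, dtype=int))
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut_height = cut_fraction * float(linkage[:, 2].max())
    raw = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")

    labels = np.zeros(len(genes), dtype=int)
    sizes: list[tuple[int, int]] = []
    for cl in np.unique(raw):
        members = raw == cl
        if members.sum() >= min_module_size:
            sizes.append((int(members.sum()), int(cl)))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, cl) in enumerate(sizes, start=1):
        labels[raw == cl] = new_label
    return ModuleAssignment(pd.Series(labels, index=genes, dtype=int))


# ---------------------------------------------------------------------------
# eigengenes and trait correlation


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise NetworkError("zero-variance gene in module")
    return (vals - mean) / sd

def module_eigengene(
    expr: pd.DataFrame, modules: ModuleAssignment
) -> EigengeneMatrix:
    """First-singular-vector eigengene per module, unit variance, sign-aligned.

    Each member gene is standardized across samples; the module eigengene is
    the first right singular vector of the standardized module submatrix,
    rescaled to unit variance and sign-flipped if needed so it correlates
    positively with the module's mean standardized profile. The proportion
    of module variance explained by the first component is reported.
    """
    rows = {}
    varexp = {}
    for mid in modules.module_ids:
        members = [g for g in modules.members(mid) if g in expr.index]
        if not members:
            raise NetworkError(f"module {mid} has no genes in the expression matrix")
        z = _standardize_rows(expr.loc[members].to_numpy(dtype=float))
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        sd = me.std(ddof=1)
        rows[mid] = me / sd if sd > 0 else me
        varexp[mid] = float(s[0] ** 2 / (s**2).sum())
    values = pd.DataFrame(rows, index=expr.columns).T
    values.index = [f"ME{m}" for m in rows]
    return EigengeneMatrix(values=values, var_explained=pd.Series(varexp))


def module_trait_correlation(
    eigengenes: EigengeneMatrix, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each numeric trait.

    Two-sided p-values come from the exact t-distribution with n - 2 degrees
    of freedom and are reported unadjusted.
    """
    records = []
    for trait in traits.columns:
        t = pd.to_numeric(traits[trait], errors="coerce").to_numpy(dtype=float)
        if np.unique(t[~np.isnan(t)]).size < 2:
            raise NetworkError(f"trait {trait!r} is constant")
        for me_name, me in eigengenes.values.iterrows():
            r, p = stats.pearsonr(me.to_numpy(), t)
            records.append(
                {"module": me_name, "trait": trait, "r": float(r), "p": float(p)}
            )
    return pd.DataFrame.from_records(records)
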