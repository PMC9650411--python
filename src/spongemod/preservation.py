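"""Permutation Z-summary module preservation between two expression datasets.

For each reference module the observed preservation statistics in the test
dataset are a density statistic (mean intramodular signed adjacency in the
test network) and a connectivity statistic (the mean of two correlations
between reference and test: of the intramodular connectivity vectors kIM,
and of the vectorized intramodular adjacency upper triangles). Both are
standardized against their permutation distribution under random relabeling
of module membership (sizes preserved) over the common genes:

    Z = (observed - mean_perm) / sd_perm,    Z_summary = (Z_density + Z_connectivity) / 2

Z_summary > 10 counts as strong preservation evidence, 2 < Z_summary <= 10
as weak-to-moderate, and Z_summary <= 2 as none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle
from .network import ModuleAssignment, adjacency, signed_similarity
from .sponge import NullModel, SpongeError, sensitivity_cc

__all__ = [
    "PreservationResult",
    "preservation_zsummary",
    "classify_evidence",
    "test_set_canonical_correlation",
]


@dataclass
class PreservationResult:
    module_id: int
    density: float
    connectivity_kim_cor: float
    connectivity_adj_cor: float
    z_density: float
    z_connectivity: float
    z_summary: float
    evidence: str
    n_permutations: int

    @property
    def connectivity(self) -> float:
        return 0.5 * (self.connectivity_kim_cor + self.connectivity_adj_cor)


def classify_evidence(z_summary: float) -> str:
    """Map a Z_summary value to its preservation evidence class.

    Boundary convention: exactly 10 is 'moderate', exactly 2 is 'none'.
    """
    if z_summary > 10:
        return "strong"
    if z_summary > 2:
        return "moderate"
    return "none"


def _module_stats(
    a_ref: np.ndarray, a_test: np.ndarray, idx: np.ndarray
) -> tuple[float, float, float]:
    """(test density, cor of kIM, cor of adjacency entries) for one gene set."""
    sub_ref = a_ref[np.ix_(idx, idx)]
    sub_test = a_test[np.ix_(idx, idx)]
    p = len(idx)
    off = ~np.eye(p, dtype=bool)
    density = float(sub_test[off].mean())
    kim_ref = sub_ref[off].reshape(p, p - 1).sum(axis=1)
    kim_test = sub_test[off].reshape(p, p - 1).sum(axis=1)
    iu = np.triu_indices(p, k=1)
    with np.errstate(invalid="ignore"):
        c_kim = np.corrcoef(kim_ref, kim_test)[0, 1]
        c_adj = np.corrcoef(sub_ref[iu], sub_test[iu])[0, 1]
    return density, float(np.nan_to_num(c_kim)), float(np.nan_to_num(c_adj))


def preservation_zsummary(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    modules: ModuleAssignment,
    power: int,
    n_perm: int = 200,
    seed: int = 0,
) -> dict[int, PreservationResult]:
    """Permutation Z statistics of module preservation in a test dataset.

    Both expression matrices are genes x samples; adjacency is rebuilt in
    each with the same signed transform and soft power (the reference run's
    power — re-selecting in the test data would confound preservation).
    Modules with fewer than 3 genes common to both datasets are skipped.
    """
    common = [g for g in ref_expr.index if g in set(test_expr.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 genes shared between reference and test")
    a_ref = adjacency(signed_similarity(ref_expr.loc[common]), power).to_numpy()
    a_test = adjacency(signed_similarity(test_expr.loc[common]), power).to_numpy()

    pos = {g: i for i, g in enumerate(common)}
    results: dict[int, PreservationResult] = {}

    module_members = {
        mid: np.array([pos[g] for g in modules.members(mid) if g in pos])
        for mid in modules.module_ids
    }
    usable = {mid: idx for mid, idx in module_members.items() if len(idx) >= 3}
    for mid in set(module_members) - set(usable):
        warnings.warn(f"module {mid}: fewer than 3 common genes; skipped")

    # each permutation reassigns the focal module's label to a uniformly
    # random same-size gene set over the common-gene universe; modules are
    # permuted independently so the Z of one module is unaffected by how the
    # others are labeled
    perm_stats = {mid: (np.empty(n_perm), np.empty(n_perm)) for mid in usable}
    n_common = len(common)
    for mid in sorted(usable):
        rng = np.random.default_rng([seed, mid])
        size = len(usable[mid])
        for b in range(n_perm):
            idx = rng.permutation(n_common)[:size]
            d, ck, ca = _module_stats(a_ref, a_test, idx)
            perm_stats[mid][0][b] = d
            perm_stats[mid][1][b] = 0.5 * (ck + ca)

    for mid, idx in sorted(usable.items()):
        d_obs, ck_obs, ca_obs = _module_stats(a_ref, a_test, idx)
        c_obs = 0.5 * (ck_obs + ca_obs)
        zs = []
        for obs, perms in ((d_obs, perm_stats[mid][0]), (c_obs, perm_stats[mid][1])):
            sd = perms.std(ddof=1)
            if sd == 0:
                # degenerate permutation distribution (e.g. test == ref makes
                # every connectivity correlation exactly 1)
                if np.isclose(obs, perms.mean()):
                    zs.append(0.0)
                else:
                    warnings.warn(
                        f"module {mid}: zero permutation spread; Z set to +/-inf"
                    )
                    zs.append(np.inf if obs > perms.mean() else -np.inf)
            else:
                zs.append((obs - perms.mean()) / sd)
        z_density, z_connectivity = zs
        z_summary = 0.5 * (z_density + z_connectivity)
        results[mid] = PreservationResult(
            module_id=mid,
            density=d_obs,
            connectivity_kim_cor=ck_obs,
            connectivity_adj_cor=ca_obs,
            z_density=float(z_density),
            z_connectivity=float(z_connectivity),
            z_summary=float(z_summary),
            evidence=classify_evidence(float(z_summary)),
            n_permutations=n_perm,
        )
    return results


def test_set_canonical_correlation(
    test_bundle: ExpressionBundle,
    lnc_members: list[str],
    mr_members: list[str],
    shared_mirnas: list[str],
    dim_cap: int | None = None,
    n_null: int = 10_000,
    seed: int = 0,
    null_model: NullModel | None = None,
) -> tuple[float, float, float]:
    """Re-test a previously identified sponge module on an independent dataset.

    Returns (canonical correlation, sensitivity canonical correlation,
    empirical null p-value) computed on the test bundle, using the module
    gene / shared-miRNA intersection with the test data. Requires at least
    3 surviving lncRNAs.
    """
    lnc = [g for g in lnc_members if g in test_bundle.lncrna.index]
    mr = [g for g in mr_members if g in test_bundle.mrna.index]
    mir = [g for g in shared_mirnas if g in test_bundle.mirna.index]
    if len(lnc) < 3:
        raise SpongeError(
            f"only {len(lnc)} module lncRNAs present in the test bundle (< 3)"
        )
    if not mr or not mir:
        raise SpongeError("module mRNAs or shared miRNAs missing from test bundle")
    parts = sensitivity_cc(
        test_bundle.lncrna.loc[lnc].T.to_numpy(),
        test_bundle.mrna.loc[mr].T.to_numpy(),
        test_bundle.mirna.loc[mir].T.to_numpy(),
        dim_cap=dim_cap,
    )
    if null_model is None:
        null_model = NullModel(n_null=n_null, seed=seed, dim_cap=dim_cap)
    p = null_model.pvalue(
        len(lnc), len(mr), len(mir), test_bundle.n_samples,
        parts.cc_lnc_mr, parts.scc,
    )
    return parts.cc_lnc_mr, parts.scc, p
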