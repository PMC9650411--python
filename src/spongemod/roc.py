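"""Single-gene ROC/AUC screening of candidate biomarker lncRNAs.

AUC is computed by the rank (Mann-Whitney) identity with ties counted 0.5.
The orientation is chosen automatically so that AUC >= 0.5, and which group
has higher expression is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .bundle import ExpressionBundle

__all__ = ["RocResult", "auc_single", "screen_lncrnas", "intersect_screens"]


@dataclass
class RocResult:
    gene_id: str
    auc: float
    direction: str  # 'case_higher' or 'control_higher'
    fpr: np.ndarray
    tpr: np.ndarray
    n_case: int
    n_control: int


def auc_single(
    values: np.ndarray, labels: np.ndarray, gene_id: str = ""
) -> RocResult:
    """ROC result for one gene's expression against binary labels.

    AUC = (R1 - n1(n1+1)/2) / (n1 n0) where R1 is the sum of case ranks with
    midranks for ties; equivalently the Mann-Whitney probability that a
    random case value exceeds a random control value, ties counting 1/2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(values)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc_case_higher = u / (n1 * n0)
    if auc_case_higher >= 0.5:
        auc, direction, oriented = auc_case_higher, "case_higher", values
    else:
        auc, direction, oriented = 1.0 - auc_case_higher, "control_higher", -values
    fpr, tpr, _ = roc_curve(labels, oriented)
    return RocResult(
        gene_id=gene_id,
        auc=float(auc),
        direction=direction,
        fpr=fpr,
        tpr=tpr,
        n_case=n1,
        n_control=n0,
    )


def screen_lncrnas(
    bundle: ExpressionBundle,
    candidates: Sequence[str],
    labels: pd.Series | None = None,
    auc_cutoff: float = 0.7,
) -> pd.DataFrame:
    """Per-candidate AUC table with a pass flag at ``auc > auc_cutoff``.

    ``labels`` defaults to the bundle's ``case`` trait. Candidates must be
    lncRNA ids present in the bundle.
    """
    if labels is None:
        labels = bundle.traits["case"]
    lab = labels.loc[bundle.sample_ids].to_numpy().astype(int)
    rows = []
    for gene in candidates:
        if gene not in bundle.lncrna.index:
            raise KeyError(f"candidate {gene!r} is not a lncRNA in the bundle")
        res = auc_single(bundle.lncrna.loc[gene].to_numpy(), lab, gene)
        rows.append(
            {
                "gene": gene,
                "auc": res.auc,
                "direction": res.direction,
                "flag": res.auc > auc_cutoff,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def intersect_screens(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine screens from several datasets: a gene passes iff it passes in all.

    Returns the per-dataset AUCs as ``auc_1..auc_k`` plus the joint flag.
    """
    if not tables:
        raise ValueError("no screen tables supplied")
    genes = tables[0].index
    out = pd.DataFrame(index=genes)
    flag = pd.Series(True, index=genes)
    for i, tab in enumerate(tables, start=1):
        aligned = tab.reindex(genes)
        out[f"auc_{i}"] = aligned["auc"]
        flag &= aligned["flag"].fillna(False).astype(bool)
    out["flag"] = flag
    return out
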