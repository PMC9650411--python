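"""Expression-level and sample-level QC filters.

Two filters are applied to an already-normalized bundle before network
construction: a minimum-expression filter (a gene must exceed an expression
floor in at least a given fraction of samples) and removal of outlier samples
whose standardized sample-network connectivity falls below a Z cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle

__all__ = [
    "PreprocessError",
    "filter_low_expression",
    "sample_outlier_z",
    "remove_outliers",
    "looks_like_raw_counts",
]


class PreprocessError(ValueError):
    pass


def filter_low_expression(
    bundle: ExpressionBundle,
    min_fraction: float = 0.5,
    expression_floor: float = 0.0,
) -> ExpressionBundle:
    """Drop genes expressed (value > floor) in fewer than ``min_fraction`` of samples.

    Applied independently within each RNA class; row order is preserved.
    Idempotent.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise PreprocessError("min_fraction must be in (0, 1]")
    kept = {}
    for name, df in bundle.matrices().items():
        frac = (df.to_numpy() > expression_floor).mean(axis=1)
        keep = frac >= min_fraction
        if not keep.any():
            raise PreprocessError(
                f"expression filter removed every gene of class '{name}'"
            )
        kept[name] = df.loc[keep]
    return ExpressionBundle(
        mrna=kept["mrna"], lncrna=kept["lncrna"], mirna=kept["mirna"],
        traits=bundle.traits,
    )


def sample_outlier_z(bundle: ExpressionBundle) -> pd.Series:
    """Standardized sample-network connectivity Z score per sample.

    Builds the sample-sample Pearson correlation matrix over the combined
    mRNA + lncRNA genes (miRNAs are excluded: a few dozen noisy rows),
    defines connectivity k_s as the sum of a sample's correlations with all
    other samples, and standardizes k across samples. Z values sum to zero
    by construction; strongly negative Z marks a sample decoupled from the
    rest of the cohort.
    """
    if bundle.n_samples < 3:
        raise PreprocessError("need at least 3 samples for outlier scoring")
    expr = bundle.coding_noncoding().to_numpy()
    sds = expr.std(axis=0)
    if (sds == 0).any():
        bad = bundle.sample_ids[int(np.argmax(sds == 0))]
        raise PreprocessError(f"sample {bad!r} has zero variance across genes")
    corr = np.corrcoef(expr, rowvar=False)
    k = corr.sum(axis=1) - 1.0  # exclude self-correlation
    sd = k.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(k)
    else:
        z = (k - k.mean()) / sd
    return pd.Series(z, index=bundle.sample_ids, name="connectivity_z")


def remove_outliers(
    bundle: ExpressionBundle, z_cutoff: float = -2.0
) -> ExpressionBundle:
    """Drop samples with connectivity Z below ``z_cutoff`` (single pass)."""
    z = sample_outlier_z(bundle)
    keep = z.index[z >= z_cutoff]
    if len(keep) < 3:
        raise PreprocessError(
            f"outlier removal would leave {len(keep)} samples (< 3)"
        )
    if len(keep) == bundle.n_samples:
        return bundle
    return bundle.subset_samples(list(keep))


def looks_like_raw_counts(df: pd.DataFrame) -> bool:
    """Heuristic raw-count alarm: integer-valued data spanning > 4 decades."""
    vals = df.to_numpy()
    if vals.size == 0:
        return False
    if not np.allclose(vals, np.round(vals)):
        return False
    positive = vals[vals > 0]
    if positive.size == 0:
        return False
    return float(positive.max()) / float(positive.min()) > 1e4
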