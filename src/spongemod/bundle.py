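"""Core data containers: expression bundles and miRNA-target matrices.

An :class:`ExpressionBundle` holds three genes x samples expression matrices
(mRNA, lncRNA, miRNA) aligned on a shared, identically ordered sample axis,
plus a per-sample trait table. A :class:`TargetMatrix` holds putative binary
miRNA->target interactions, partitioned into a miRNA x mRNA and a
miRNA x lncRNA incidence block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionBundle", "TargetMatrix", "BundleValidationError"]


class BundleValidationError(ValueError):
    """Raised when a bundle or target matrix violates a structural invariant."""


@dataclass
class ExpressionBundle:
    """Three aligned genes x samples expression matrices plus sample traits.

    Parameters
    ----------
    mrna, lncrna, mirna : pandas.DataFrame
        Expression matrices (rows = gene ids, columns = sample ids). All three
        must share the same column sequence.
    traits : pandas.DataFrame
        Indexed by sample id, in the same order as the expression columns.
        Conventional columns: ``diagnosis`` (integer code, e.g. ASD=1, SCZ=2,
        BD=3) and ``case`` (0/1 flag).
    """

    mrna: pd.DataFrame
    lncrna: pd.DataFrame
    mirna: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        samples = list(self.mrna.columns)
        for name, df in (("lncrna", self.lncrna), ("mirna", self.mirna)):
            if list(df.columns) != samples:
                raise BundleValidationError(
                    f"sample ids of '{name}' do not match the mRNA matrix"
                )
        if list(self.traits.index) != samples:
            raise BundleValidationError(
                "trait table index does not match the expression sample ids"
            )
        seen: set[str] = set()
        for name, df in self.matrices().items():
            ids = df.index
            if ids.has_duplicates:
                dup = ids[ids.duplicated()][0]
                raise BundleValidationError(
                    f"duplicate gene id {dup!r} within class '{name}'"
                )
            overlap = seen.intersection(ids)
            if overlap:
                raise BundleValidationError(
                    f"gene id {sorted(overlap)[0]!r} appears in more than one RNA class"
                )
            seen.update(ids)
            if not np.isfinite(df.to_numpy()).all():
                raise BundleValidationError(f"non-finite values in class '{name}'")

    # -- convenience accessors ---------------------------------------------

    def matrices(self) -> dict[str, pd.DataFrame]:
        return {"mrna": self.mrna, "lncrna": self.lncrna, "mirna": self.mirna}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mrna.columns)

    @property
    def n_samples(self) -> int:
        return self.mrna.shape[1]

    def gene_class(self, gene_id: str) -> str:
        for name, df in self.matrices().items():
            if gene_id in df.index:
                return name
        raise KeyError(gene_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionBundle":
        ids = list(sample_ids)
        return ExpressionBundle(
            mrna=self.mrna[ids],
            lncrna=self.lncrna[ids],
            mirna=self.mirna[ids],
            traits=self.traits.loc[ids],
        )

    def coding_noncoding(self) -> pd.DataFrame:
        """mRNA and lncRNA rows stacked (the gene universe of the network)."""
        return pd.concat([self.mrna, self.lncrna], axis=0)


@dataclass
class TargetMatrix:
    """Binary putative miRNA->target incidence, split by target RNA class.

    ``mrna_targets`` and ``lncrna_targets`` are DataFrames with miRNA ids as
    rows and target gene ids as columns, entries in {0, 1}.
    """

    mrna_targets: pd.DataFrame
    lncrna_targets: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("mrna", self.mrna_targets), ("lncrna", self.lncrna_targets)):
            vals = df.to_numpy()
            if vals.size and not np.isin(vals, (0, 1)).all():
                raise BundleValidationError(
                    f"miRNA-{name} target matrix is not binary"
                )

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(set(self.mrna_targets.index) | set(self.lncrna_targets.index))

    def mirnas_targeting(self, genes: Iterable[str], kind: str) -> set[str]:
        """miRNA ids with at least one edge into ``genes`` of class ``kind``."""
        block = self.mrna_targets if kind == "mrna" else self.lncrna_targets
        cols = [g for g in genes if g in block.columns]
        if not cols:
            return set()
        hit = block[cols].to_numpy().sum(axis=1) > 0
        return set(block.index[hit])

    def targets_of(self, mirna_id: str, kind: str) -> set[str]:
        block = self.mrna_targets if kind == "mrna" else self.lncrna_targets
        if mirna_id not in block.index:
            return set()
        row = block.loc[mirna_id]
        return set(row.index[row.to_numpy() > 0])

    def to_edge_list(self) -> pd.DataFrame:
        """Two-column (mirna, target) edge list over both blocks."""
        frames = []
        for block in (self.lncrna_targets, self.mrna_targets):
            mir, tgt = np.nonzero(block.to_numpy())
            frames.append(
                pd.DataFrame(
                    {
                        "mirna": block.index.to_numpy()[mir],
                        "target": block.columns.to_numpy()[tgt],
                    }
                )
            )
        edges = pd.concat(frames, ignore_index=True)
        return edges.sort_values(["mirna", "target"], ignore_index=True)
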