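"""Readers and writers for the interchange formats.

Expression matrices travel as TSV (first column the gene id, header row the
sample ids), traits as a TSV keyed by sample id, target interactions as a
2-column (miRNA, target) TSV edge list, and ground truth as JSON. All
writers emit a header and a stable column order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle, TargetMatrix
from .simulate import GroundTruth, ModuleSpec, SimulationSpec

logger = logging.getLogger("spongemod")

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_bundle",
    "write_bundle",
    "read_target_edges",
    "write_target_edges",
    "read_ground_truth",
    "write_ground_truth",
]

BUNDLE_FILES = {"mrna": "mrna.tsv", "lncrna": "lncrna.tsv", "mirna": "mirna.tsv"}
TRAITS_FILE = "traits.tsv"


class ParseError(ValueError):
    pass


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix from TSV; validates shape, ids, and numerics."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file or missing header")
        columns = header.split("\t")[1:]
        n_cols = len(columns)
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(parts)}"
                )
            gene = parts[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if not np.isfinite(values).all():
                raise ParseError(f"{path}:{lineno}: non-finite value")
            ids.append(gene)
            rows.append(values)
    return pd.DataFrame(rows, index=ids, columns=columns)


def write_expression_tsv(df: pd.DataFrame, path: str | Path, digits: int = 6) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=f"%.{digits}f")


def read_bundle(directory: str | Path) -> ExpressionBundle:
    directory = Path(directory)
    mats = {k: read_expression_tsv(directory / f) for k, f in BUNDLE_FILES.items()}
    traits = pd.read_csv(directory / TRAITS_FILE, sep="\t", index_col=0)
    return ExpressionBundle(traits=traits, **mats)


def write_bundle(bundle: ExpressionBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, fname in BUNDLE_FILES.items():
        write_expression_tsv(bundle.matrices()[kind], directory / fname)
    traits = bundle.traits.copy()
    traits.index.name = "sample"
    traits.to_csv(directory / TRAITS_FILE, sep="\t")


def read_target_edges(
    path: str | Path,
    known_mirnas: list[str],
    known_lncrnas: list[str],
    known_mrnas: list[str],
) -> TargetMatrix:
    """Binary target matrix from a (miRNA, target) TSV edge list.

    Edges whose miRNA or target id is unknown are skipped (counted and
    logged, not fatal); duplicate edges collapse to one. The result is
    partitioned into the miRNA x mRNA and miRNA x lncRNA blocks.
    """
    path = Path(path)
    mir_set, lnc_set, mr_set = set(known_mirnas), set(known_lncrnas), set(known_mrnas)
    mr_block = pd.DataFrame(0, index=list(known_mirnas), columns=list(known_mrnas), dtype=np.int8)
    lnc_block = pd.DataFrame(0, index=list(known_mirnas), columns=list(known_lncrnas), dtype=np.int8)
    n_edges = n_skipped = 0
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 fields")
            mir, target = parts[0], parts[1]
            if mir in mir_set and target in mr_set:
                mr_block.loc[mir, target] = 1
                n_edges += 1
            elif mir in mir_set and target in lnc_set:
                lnc_block.loc[mir, target] = 1
                n_edges += 1
            else:
                n_skipped += 1
    if n_skipped:
        logger.info("read_target_edges: skipped %d edges with unknown ids", n_skipped)
    if n_edges == 0:
        raise ParseError(f"{path}: no usable edges after id filtering")
    return TargetMatrix(mrna_targets=mr_block, lncrna_targets=lnc_block)


def write_target_edges(targets: TargetMatrix, path: str | Path) -> None:
    edges = targets.to_edge_list()
    edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    spec_dict = dataclasses.asdict(truth.spec)
    spec_dict["modules"] = [dataclasses.asdict(m) for m in truth.spec.modules]
    payload = {
        "spec": spec_dict,
        "module_labels": truth.module_labels,
        "is_sponge": {str(k): v for k, v in truth.is_sponge.items()},
        "shared_mirnas": {str(k): v for k, v in truth.shared_mirnas.items()},
        "biomarker_effects": truth.biomarker_effects,
        "baselines": truth.baselines,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    spec_dict = dict(payload["spec"])
    spec_dict["modules"] = tuple(ModuleSpec(**m) for m in spec_dict["modules"])
    spec_dict["baseline_range"] = tuple(spec_dict["baseline_range"])
    spec = SimulationSpec(**spec_dict)
    return GroundTruth(
        spec=spec,
        module_labels={k: int(v) for k, v in payload["module_labels"].items()},
        is_sponge={int(k): bool(v) for k, v in payload["is_sponge"].items()},
        shared_mirnas={int(k): list(v) for k, v in payload["shared_mirnas"].items()},
        biomarker_effects={k: float(v) for k, v in payload["biomarker_effects"].items()},
        baselines={k: float(v) for k, v in payload["baselines"].items()},
    )
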