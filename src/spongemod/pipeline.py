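"""Top-level pipeline: preprocess -> network -> sponge (-> preserve, roc).

`run_pipeline` wires the stages together, writes every stage artifact as TSV
plus a machine-readable JSON manifest (parameters, derived per-stage seeds,
per-stage counts), and is idempotent for a fixed config and seed. The single
global seed is expanded into independent per-stage seeds with numpy's
SeedSequence so stages can be re-run in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import ExpressionBundle, TargetMatrix
from .network import (
    ModuleAssignment,
    adjacency,
    cut_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    signed_similarity,
    topological_overlap,
)
from .preprocess import filter_low_expression, looks_like_raw_counts, remove_outliers
from .preservation import preservation_zsummary
from .roc import screen_lncrnas
from .sponge import SpongeModuleResult, identify_sponge_modules

logger = logging.getLogger("spongemod")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stage_seeds"]

_STAGES = ("simulate", "preprocess", "network", "sponge", "preserve", "roc")


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into deterministic per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {stage: int(s % 2**31) for stage, s in zip(_STAGES, state)}


@dataclass
class RunConfig:
    """All stage parameters of the pipeline, with study defaults.

    Defaults mirror the reference analysis conventions: 50% expression
    filter, connectivity-Z outlier cutoff -2, soft power 18, minimum module
    size 50, null model with 10^6 sampled datasets, 200 preservation
    permutations, alpha 0.05.
    """

    # QC
    min_fraction: float = 0.5
    expression_floor: float = 0.0
    z_cutoff: float = -2.0
    # network
    power: int | str = 18  # integer, or 'auto' for scale-free selection
    r2_cutoff: float = 0.8
    min_module_size: int = 50
    cut_fraction: float = 0.99
    # sponge test
    min_lncrnas: int = 3
    sharing_alpha: float = 0.05
    adj_alpha: float = 0.05
    dim_cap: int | None = None  # None -> floor(n_samples / 3)
    n_null: int = 1_000_000
    # preservation / roc
    n_perm: int = 200
    auc_cutoff: float = 0.7
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.power != "auto" and int(self.power) < 1:
            raise ValueError("power must be a positive integer or 'auto'")
        for name in ("sharing_alpha", "adj_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    bundle: ExpressionBundle
    modules: ModuleAssignment
    power: int
    sponge_results: list[SpongeModuleResult]
    manifest: dict
    preservation: dict | None = None
    roc_table: pd.DataFrame | None = None


def sponge_summary_table(results: list[SpongeModuleResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "module": r.module_id,
                "n_lncrna": r.n_lncrna,
                "n_mrna": r.n_mrna,
                "N1": r.counts.n1,
                "M1": r.counts.m1,
                "K1": r.counts.k1,
                "L1": r.counts.l1,
                "sharing_p": r.sharing_p,
                "cc_lnc_mr": r.cc_lnc_mr,
                "cc_mir_mr": r.cc_mir_mr,
                "cc_mir_lnc": r.cc_mir_lnc,
                "pcc": r.pcc,
                "scc": r.scc,
                "null_p": r.null_p,
                "adj_p": r.adj_p,
                "is_sponge": r.is_sponge,
                "n_interactions": len(r.interactions),
            }
        )
    return pd.DataFrame(rows)


def interaction_table(results: list[SpongeModuleResult]) -> pd.DataFrame:
    rows = [
        {
            "module": r.module_id,
            "lncrna": lnc,
            "mrna": mr,
            "shared_mirnas": ";".join(mirs),
        }
        for r in results
        for lnc, mr, mirs in r.interactions
    ]
    return pd.DataFrame(rows, columns=["module", "lncrna", "mrna", "shared_mirnas"])


def run_pipeline(
    bundle: ExpressionBundle,
    targets: TargetMatrix,
    config: RunConfig,
    out_dir: str | Path | None = None,
    test_bundle: ExpressionBundle | None = None,
    roc_candidates: list[str] | None = None,
) -> PipelineResult:
    """Execute the full inference pipeline on an expression bundle.

    Stages: QC filters -> signed network + module detection + eigengenes ->
    three-condition sponge-module test; optionally module preservation
    against ``test_bundle`` and ROC screening of ``roc_candidates`` (default:
    the lncRNAs of flagged sponge modules). Writes all stage tables and a
    run manifest under ``out_dir`` when given.
    """
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config": {
            k: (v if not isinstance(v, Path) else str(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": seeds,
        "counts": {},
    }

    # ---- preprocess
    for name, df in bundle.matrices().items():
        if looks_like_raw_counts(df):
            warnings.warn(
                f"matrix '{name}' looks like raw counts (integers spanning "
                ">4 decades); the pipeline expects normalized log-scale data"
            )
    n_genes_before = {k: df.shape[0] for k, df in bundle.matrices().items()}
    n_samples_before = bundle.n_samples
    bundle = filter_low_expression(bundle, config.min_fraction, config.expression_floor)
    bundle = remove_outliers(bundle, config.z_cutoff)
    manifest["counts"]["genes_kept"] = {
        k: df.shape[0] for k, df in bundle.matrices().items()
    }
    manifest["counts"]["genes_before"] = n_genes_before
    manifest["counts"]["samples_dropped"] = n_samples_before - bundle.n_samples
    logger.info(
        "preprocess: kept %s genes, dropped %d samples",
        manifest["counts"]["genes_kept"], manifest["counts"]["samples_dropped"],
    )

    # ---- network (mRNA + lncRNA jointly; miRNAs never enter the network)
    expr = bundle.coding_noncoding()
    sim = signed_similarity(expr)
    if config.power == "auto":
        st = pick_soft_threshold(sim, r2_cutoff=config.r2_cutoff)
        power = st.power
        manifest["soft_threshold"] = {
            "selected": power,
            "warning": st.warning,
            "fits": {str(p): f for p, f in st.fits.items()},
        }
    else:
        power = int(config.power)
        manifest["soft_threshold"] = {"selected": power, "forced": True}
    tom = topological_overlap(adjacency(sim, power))
    modules = cut_modules(tom, config.min_module_size, config.cut_fraction)
    eig = module_eigengene(expr, modules)
    trait_cor = module_trait_correlation(eig, bundle.traits)
    manifest["counts"]["modules_found"] = len(modules.module_ids)
    logger.info("network: power=%d, %d modules", power, len(modules.module_ids))

    # ---- sponge identification
    results = identify_sponge_modules(
        bundle,
        modules,
        targets,
        min_lncrnas=config.min_lncrnas,
        sharing_alpha=config.sharing_alpha,
        adj_alpha=config.adj_alpha,
        dim_cap=config.dim_cap,
        n_null=config.n_null,
        seed=seeds["sponge"],
    )
    flagged = [r for r in results if r.is_sponge]
    manifest["counts"]["candidates_tested"] = len(results)
    manifest["counts"]["sponges_flagged"] = len(flagged)
    manifest["counts"]["interactions"] = sum(len(r.interactions) for r in flagged)
    logger.info(
        "sponge: %d candidates, %d flagged, %d interactions",
        len(results), len(flagged), manifest["counts"]["interactions"],
    )

    # ---- optional preservation
    preservation = None
    if test_bundle is not None:
        preservation = preservation_zsummary(
            expr,
            test_bundle.coding_noncoding(),
            modules,
            power=power,
            n_perm=config.n_perm,
            seed=seeds["preserve"],
        )
        manifest["counts"]["modules_preserved_strong"] = sum(
            1 for r in preservation.values() if r.evidence == "strong"
        )

    # ---- optional ROC screen
    roc_table = None
    if roc_candidates is None:
        roc_candidates = sorted(
            {
                g
                for r in flagged
                for g in modules.members(r.module_id)
                if g in bundle.lncrna.index
            }
        )
    if roc_candidates and "case" in bundle.traits.columns:
        roc_table = screen_lncrnas(
            bundle, roc_candidates, auc_cutoff=config.auc_cutoff
        )
        manifest["counts"]["roc_flagged"] = int(roc_table["flag"].sum())

    result = PipelineResult(
        bundle=bundle,
        modules=modules,
        power=power,
        sponge_results=results,
        manifest=manifest,
        preservation=preservation,
        roc_table=roc_table,
    )
    if out_dir is not None:
        _write_outputs(result, eig, trait_cor, Path(out_dir))
    return result


def _write_outputs(
    result: PipelineResult,
    eig,
    trait_cor: pd.DataFrame,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = result.bundle
    classes = pd.Series(
        {g: name for name, df in bundle.matrices().items() for g in df.index}
    )
    assign = pd.DataFrame(
        {
            "gene_id": result.modules.labels.index,
            "class": classes.reindex(result.modules.labels.index).to_numpy(),
            "module": result.modules.labels.to_numpy(),
        }
    )
    assign.to_csv(out_dir / "modules.tsv", sep="\t", index=False)
    eig.values.to_csv(out_dir / "eigengenes.tsv", sep="\t")
    trait_cor.to_csv(out_dir / "module_trait_correlation.tsv", sep="\t", index=False)
    sponge_summary_table(result.sponge_results).to_csv(
        out_dir / "sponge_modules.tsv", sep="\t", index=False
    )
    interaction_table(result.sponge_results).to_csv(
        out_dir / "interactions.tsv", sep="\t", index=False
    )
    from .sponge import lncrna_outdegree

    all_inter = [i for r in result.sponge_results for i in r.interactions]
    lncrna_outdegree(all_inter).to_csv(
        out_dir / "lncrna_outdegree.tsv", sep="\t", index=False
    )
    if result.preservation is not None:
        pres = pd.DataFrame(
            [
                {
                    "module": r.module_id,
                    "density": r.density,
                    "connectivity_kim_cor": r.connectivity_kim_cor,
                    "connectivity_adj_cor": r.connectivity_adj_cor,
                    "z_density": r.z_density,
                    "z_connectivity": r.z_connectivity,
                    "z_summary": r.z_summary,
                    "evidence": r.evidence,
                }
                for r in result.preservation.values()
            ]
        )
        pres.to_csv(out_dir / "preservation.tsv", sep="\t", index=False)
    if result.roc_table is not None:
        result.roc_table.to_csv(out_dir / "roc_screen.tsv", sep="\t")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
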