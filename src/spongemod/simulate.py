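"""Synthetic expression bundles with planted miRNA sponge modules.

The generator emulates a post-normalization, log-scale multi-omic expression
bundle (mRNA + lncRNA + miRNA on shared samples) in which a known subset of
co-expression modules is miRNA-mediated. Each module m has a latent activity
factor f_m and, if it is a true sponge module, a set of shared miRNAs whose
expression u_k feeds *negatively* into every member gene (miRNAs repress
their targets; the two ceRNA classes therefore correlate positively with
each other and negatively with the shared miRNAs):

    lncRNA i in m:  x_i(s) = b_i + alpha_m * f_m(s) - beta_m * sum_k u_k(s) + eps
    mRNA   j in m:  y_j(s) = b_j + alpha_m * f_m(s) - beta_m * sum_k u_k(s) + eps

with f_m, u_k ~ N(0,1) per sample, eps ~ N(0, noise_sd^2), and b a per-gene
baseline abundance. A decoy module has beta_m = 0: co-expressed, but its
lncRNA-mRNA correlation owes nothing to miRNAs, so its sensitivity canonical
correlation is zero in population. Background genes are baseline plus unit
Gaussian noise. Designated biomarker lncRNAs receive an additive case-sample
shift expressed in noise-SD units.

The putative target matrix contains every planted edge (each shared miRNA
targets all lncRNAs and mRNAs of its module) plus independent Bernoulli
background edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle, TargetMatrix

__all__ = [
    "ModuleSpec",
    "SimulationSpec",
    "GroundTruth",
    "SimulationSpecError",
    "generate_bundle",
    "generate_test_dataset",
    "default_spec",
]


class SimulationSpecError(ValueError):
    """Raised when a simulation spec is internally inconsistent."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``factor_loading`` (alpha) scales the shared latent factor;
    ``mirna_loading`` (beta) scales the summed shared-miRNA signal. A module
    with ``mirna_loading == 0`` is a decoy: it may still own planted target
    edges (``n_shared_mirna > 0``) but its expression is miRNA-independent.
    """

    n_lncrna: int
    n_mrna: int
    n_shared_mirna: int = 0
    factor_loading: float = 1.0
    mirna_loading: float = 0.0
    loading_spread: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading_spread < 1.0:
            raise SimulationSpecError("loading_spread must be in [0, 1)")
        if self.n_lncrna < 1 or self.n_mrna < 1:
            raise SimulationSpecError("module needs at least 1 lncRNA and 1 mRNA")
        if self.n_shared_mirna < 0:
            raise SimulationSpecError("n_shared_mirna must be non-negative")
        if self.mirna_loading < 0:
            raise SimulationSpecError("mirna_loading must be non-negative")
        if self.mirna_loading > 0 and self.n_shared_mirna == 0:
            raise SimulationSpecError(
                "mirna_loading > 0 requires at least one shared miRNA"
            )

    @property
    def is_sponge(self) -> bool:
        return self.mirna_loading > 0 and self.n_shared_mirna >= 1

    @property
    def n_genes(self) -> int:
        return self.n_lncrna + self.n_mrna


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic expression bundle."""

    n_samples: int = 150
    n_mrna: int = 2000
    n_lncrna: int = 300
    n_mirna: int = 35
    modules: tuple[ModuleSpec, ...] = ()
    background_target_density: float = 0.002
    noise_sd: float = 1.0
    case_fraction: float = 0.5
    biomarker_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "biomarker_effects", dict(self.biomarker_effects))
        for name in ("n_samples", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise SimulationSpecError(f"{name} must be positive")
        if not 0.0 <= self.background_target_density <= 1.0:
            raise SimulationSpecError("background_target_density must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be non-negative")
        if not 0.0 < self.case_fraction < 1.0:
            raise SimulationSpecError("case_fraction must be in (0, 1)")
        for total, attr, cls in (
            (self.n_lncrna, "n_lncrna", "lncRNA"),
            (self.n_mrna, "n_mrna", "mRNA"),
            (self.n_mirna, "n_shared_mirna", "miRNA"),
        ):
            used = sum(getattr(m, attr) for m in self.modules)
            if used > total:
                raise SimulationSpecError(
                    f"module {cls} counts ({used}) exceed the class total ({total})"
                )

    # -- gene naming / layout ---------------------------------------------

    def lncrna_ids(self) -> list[str]:
        return [f"lnc_{i + 1:04d}" for i in range(self.n_lncrna)]

    def mrna_ids(self) -> list[str]:
        return [f"mR_{i + 1:04d}" for i in range(self.n_mrna)]

    def mirna_ids(self) -> list[str]:
        return [f"miR_{i + 1:03d}" for i in range(self.n_mirna)]

    def sample_ids(self, n: int | None = None) -> list[str]:
        n = self.n_samples if n is None else n
        return [f"S{i + 1:03d}" for i in range(n)]

    def module_slots(self) -> list[dict[str, slice]]:
        """Row slices occupied by each module, in class-local coordinates.

        Modules claim consecutive rows from the top of each class matrix;
        rows beyond the claimed blocks are background genes.
        """
        slots = []
        lo_l = lo_m = lo_r = 0
        for mspec in self.modules:
            slots.append(
                {
                    "lncrna": slice(lo_l, lo_l + mspec.n_lncrna),
                    "mrna": slice(lo_m, lo_m + mspec.n_mrna),
                    "mirna": slice(lo_r, lo_r + mspec.n_shared_mirna),
                }
            )
            lo_l += mspec.n_lncrna
            lo_m += mspec.n_mrna
            lo_r += mspec.n_shared_mirna
        return slots


@dataclass
class GroundTruth:
    """Planted structure of a generated bundle.

    ``module_labels`` maps every mRNA/lncRNA id to its planted module
    (1-based; 0 = background). ``shared_mirnas`` lists each module's planted
    shared miRNA ids. Baselines are retained so that test datasets can be
    regenerated from the same generative law.
    """

    spec: SimulationSpec
    module_labels: dict[str, int]
    is_sponge: dict[int, bool]
    shared_mirnas: dict[int, list[str]]
    biomarker_effects: dict[str, float]
    baselines: dict[str, float]

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.is_sponge)

    def members(self, module_id: int, kind: str | None = None) -> list[str]:
        prefix = {"lncrna": "lnc_", "mrna": "mR_"}.get(kind, "")
        return [
            g
            for g, lab in self.module_labels.items()
            if lab == module_id and g.startswith(prefix)
        ]


# ---------------------------------------------------------------------------
# generation


def _gene_weights(count: int, spread: float) -> np.ndarray:
    """Fixed per-gene signal multipliers giving the module a hub gradient.

    Deterministic by gene position (not random), so regenerating a module
    with fresh noise reproduces the same connectivity pattern; spread 0
    makes all genes exchangeable.
    """
    if count == 1:
        return np.ones(1)
    return np.linspace(1.0 - spread, 1.0 + spread, count)


def _draw_module_signal(
    rng: np.random.Generator, mspec: ModuleSpec, n: int, noise_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fresh (lncRNA rows, mRNA rows, shared-miRNA rows) for one module."""
    f = rng.standard_normal(n)
    u = rng.standard_normal((mspec.n_shared_mirna, n))
    signal = mspec.factor_loading * f - mspec.mirna_loading * u.sum(axis=0)
    w_lnc = _gene_weights(mspec.n_lncrna, mspec.loading_spread)
    w_mr = _gene_weights(mspec.n_mrna, mspec.loading_spread)
    lnc = w_lnc[:, None] * signal + noise_sd * rng.standard_normal((mspec.n_lncrna, n))
    mr = w_mr[:, None] * signal + noise_sd * rng.standard_normal((mspec.n_mrna, n))
    return lnc, mr, u


def _apply_biomarker_shifts(
    lnc: np.ndarray,
    lnc_ids: Sequence[str],
    effects: Mapping[str, float],
    case: np.ndarray,
    noise_sd: float,
) -> None:
    index = {g: i for i, g in enumerate(lnc_ids)}
    for gene, effect in effects.items():
        if gene not in index:
            raise SimulationSpecError(f"biomarker id {gene!r} is not a lncRNA id")
        lnc[index[gene], case.astype(bool)] += effect * noise_sd


def generate_bundle(
    spec: SimulationSpec,
) -> tuple[ExpressionBundle, TargetMatrix, GroundTruth]:
    """Generate a bundle, its putative target matrix, and the ground truth.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lnc_ids, mr_ids, mir_ids = spec.lncrna_ids(), spec.mrna_ids(), spec.mirna_ids()

    lo, hi = spec.baseline_range
    base_lnc = rng.uniform(lo, hi, spec.n_lncrna)
    base_mr = rng.uniform(lo, hi, spec.n_mrna)
    base_mir = rng.uniform(lo, hi, spec.n_mirna)

    # background: unit-variance noise around the baseline
    L = rng.standard_normal((spec.n_lncrna, n))
    M = rng.standard_normal((spec.n_mrna, n))
    R = rng.standard_normal((spec.n_mirna, n))

    slots = spec.module_slots()
    for mspec, slot in zip(spec.modules, slots):
        lnc, mr, u = _draw_module_signal(rng, mspec, n, spec.noise_sd)
        L[slot["lncrna"]] = lnc
        M[slot["mrna"]] = mr
        R[slot["mirna"]] = u

    # traits: exact case count, random assignment; 3-level diagnosis code
    # (ASD=1, SCZ=2, BD=3) drawn independently of case status
    n_case = int(round(spec.case_fraction * n))
    n_case = min(max(n_case, 1), n - 1)
    case = np.zeros(n, dtype=int)
    case[rng.permutation(n)[:n_case]] = 1
    diagnosis = rng.integers(1, 4, size=n)

    _apply_biomarker_shifts(L, lnc_ids, spec.biomarker_effects, case, spec.noise_sd)

    L += base_lnc[:, None]
    M += base_mr[:, None]
    R += base_mir[:, None]

    # putative targeting: background Bernoulli edges, then planted edges
    tmat_mr = (
        rng.random((spec.n_mirna, spec.n_mrna)) < spec.background_target_density
    ).astype(np.int8)
    tmat_lnc = (
        rng.random((spec.n_mirna, spec.n_lncrna)) < spec.background_target_density
    ).astype(np.int8)
    for slot in slots:
        tmat_mr[slot["mirna"], slot["mrna"]] = 1
        tmat_lnc[slot["mirna"], slot["lncrna"]] = 1

    samples = spec.sample_ids()
    bundle = ExpressionBundle(
        mrna=pd.DataFrame(M, index=mr_ids, columns=samples),
        lncrna=pd.DataFrame(L, index=lnc_ids, columns=samples),
        mirna=pd.DataFrame(R, index=mir_ids, columns=samples),
        traits=pd.DataFrame(
            {"diagnosis": diagnosis, "case": case}, index=pd.Index(samples, name="sample"),
        ),
    )
    targets = TargetMatrix(
        mrna_targets=pd.DataFrame(tmat_mr, index=mir_ids, columns=mr_ids),
        lncrna_targets=pd.DataFrame(tmat_lnc, index=mir_ids, columns=lnc_ids),
    )

    module_labels = {g: 0 for g in lnc_ids + mr_ids}
    shared: dict[int, list[str]] = {}
    sponge: dict[int, bool] = {}
    for mid, (mspec, slot) in enumerate(zip(spec.modules, slots), start=1):
        for g in lnc_ids[slot["lncrna"]] + mr_ids[slot["mrna"]]:
            module_labels[g] = mid
        shared[mid] = mir_ids[slot["mirna"]]
        sponge[mid] = mspec.is_sponge

    baselines = dict(zip(lnc_ids, base_lnc))
    baselines.update(zip(mr_ids, base_mr))
    baselines.update(zip(mir_ids, base_mir))
    truth = GroundTruth(
        spec=spec,
        module_labels=module_labels,
        is_sponge=sponge,
        shared_mirnas=shared,
        biomarker_effects=dict(spec.biomarker_effects),
        baselines=baselines,
    )
    return bundle, targets, truth


def generate_test_dataset(
    bundle: ExpressionBundle,
    truth: GroundTruth,
    preserve: set[int],
    seed: int,
    n_samples: int | None = None,
) -> ExpressionBundle:
    """Perturbed copy of a bundle for preservation analysis.

    Modules in ``preserve`` are regenerated from the same generative law with
    fresh latent factors and noise (co-expression structure preserved). Every
    other gene row is independently scrambled across samples (same-size
    output: a permutation of the row; resized output: iid resampling with
    replacement), which preserves each gene's marginal distribution but
    destroys all between-gene structure.
    """
    spec = truth.spec
    unknown = set(preserve) - set(truth.module_ids)
    if unknown:
        raise KeyError(f"unknown module id(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_out = bundle.n_samples if n_samples is None else n_samples
    resized = n_out != bundle.n_samples

    def scrambled(row: np.ndarray) -> np.ndarray:
        if resized:
            return rng.choice(row, size=n_out, replace=True)
        return rng.permutation(row)

    mats = {
        name: np.vstack([scrambled(r) for r in df.to_numpy()])
        for name, df in bundle.matrices().items()
    }

    if resized:
        samples = [f"T{i + 1:03d}" for i in range(n_out)]
        n_case = min(max(int(round(spec.case_fraction * n_out)), 1), n_out - 1)
        case = np.zeros(n_out, dtype=int)
        case[rng.permutation(n_out)[:n_case]] = 1
        traits = pd.DataFrame(
            {"diagnosis": rng.integers(1, 4, size=n_out), "case": case},
            index=pd.Index(samples, name="sample"),
        )
    else:
        samples = bundle.sample_ids
        traits = bundle.traits.copy()
        case = traits["case"].to_numpy()

    lnc_pos = {g: i for i, g in enumerate(bundle.lncrna.index)}
    mr_pos = {g: i for i, g in enumerate(bundle.mrna.index)}
    mir_pos = {g: i for i, g in enumerate(bundle.mirna.index)}
    base = truth.baselines

    for mid in sorted(preserve):
        mspec = spec.modules[mid - 1]
        lnc_members = truth.members(mid, "lncrna")
        mr_members = truth.members(mid, "mrna")
        lnc, mr, u = _draw_module_signal(rng, mspec, n_out, spec.noise_sd)
        effects = {
            g: e for g, e in truth.biomarker_effects.items() if g in lnc_members
        }
        _apply_biomarker_shifts(lnc, lnc_members, effects, case, spec.noise_sd)
        for i, g in enumerate(lnc_members):
            mats["lncrna"][lnc_pos[g]] = lnc[i] + base[g]
        for j, g in enumerate(mr_members):
            mats["mrna"][mr_pos[g]] = mr[j] + base[g]
        for k, g in enumerate(truth.shared_mirnas[mid]):
            mats["mirna"][mir_pos[g]] = u[k] + base[g]

    return ExpressionBundle(
        mrna=pd.DataFrame(mats["mrna"], index=bundle.mrna.index, columns=samples),
        lncrna=pd.DataFrame(mats["lncrna"], index=bundle.lncrna.index, columns=samples),
        mirna=pd.DataFrame(mats["mirna"], index=bundle.mirna.index, columns=samples),
        traits=traits,
    )


# ---------------------------------------------------------------------------
# default study conditions


def default_spec(seed: int = 0) -> SimulationSpec:
    """The default synthetic study: 4 planted sponge modules and 3 decoys.

    Desk-scale totals (150 samples; 2,000 mRNAs, 300 lncRNAs, 35 miRNAs —
    the miRNA count matching the size of a typical post-filter brain miRNA
    panel). Sponge modules use factor loading 0.6 and miRNA loading 0.8 with
    3 shared miRNAs, so roughly 84% of the module covariance is
    miRNA-mediated; decoys use factor loading 1.51, matching the sponge
    modules' within-module correlation (~0.7) without any miRNA term. All
    modules carry a 25% hub gradient (loading spread) so intramodular
    connectivity has a stable, reproducible pattern. Two decoys own planted
    target edges (they pass the miRNA-sharing test and must be rejected by
    the sensitivity-canonical-correlation null test); one has none. Module 4
    carries the planted biomarkers: its 45 lncRNAs are shifted by 1.5
    noise-SD in cases; two background lncRNAs get a clean 2.0 noise-SD shift.
    """
    sponge = dict(
        n_shared_mirna=3, factor_loading=0.6, mirna_loading=0.8, loading_spread=0.25
    )
    decoy = dict(
        n_shared_mirna=3, factor_loading=1.51, mirna_loading=0.0, loading_spread=0.25
    )
    modules = (
        ModuleSpec(n_lncrna=10, n_mrna=50, **sponge),
        ModuleSpec(n_lncrna=10, n_mrna=50, **sponge),
        ModuleSpec(n_lncrna=10, n_mrna=50, **sponge),
        ModuleSpec(n_lncrna=45, n_mrna=15, **sponge),
        ModuleSpec(n_lncrna=10, n_mrna=50, **decoy),
        ModuleSpec(n_lncrna=10, n_mrna=50, **decoy),
        ModuleSpec(
            n_lncrna=10, n_mrna=50, n_shared_mirna=0,
            factor_loading=1.51, loading_spread=0.25,
        ),
    )
    # module 4 lncRNAs occupy rows 31..75 (1-based) of the lncRNA matrix
    effects = {f"lnc_{i:04d}": 1.5 for i in range(31, 76)}
    effects["lnc_0299"] = 2.0
    effects["lnc_0300"] = 2.0
    return SimulationSpec(modules=modules, biomarker_effects=effects, seed=seed)
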