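"""Synthetic case/control cohorts with planted structure.

The generator emulates a normalized log-scale brain transcriptome cohort of
three disorders (AUT, SCZ, BPD) plus shared controls, with the features the
downstream analyses rely on:

* planted co-expression modules (rank-1 latent factors with positive
  loadings, so signed networks can recover them),
* planted *aberrantly expressed* gene sets — for a fraction ``rho`` of a
  disorder's cases, the residual SD of the member genes is multiplied by
  ``tau``.  This inflates between-individual dispersion with per-case random
  sign structure and no common mean shift, which is the premise of the
  dispersion-based screen (case heterogeneity rather than a shared
  up/down-regulation),
* two source batches (the AUT cases and their controls form batch "I"; SCZ
  and BPD cases share the batch "II" controls), batch offsets, and the
  age/sex/brain-region covariates,
* disease-uncorrelated hidden factors.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` substreams, so a fixed seed gives bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSet, GeneSetCollection

__all__ = [
    "CohortConfig",
    "PlantedSet",
    "PlantedModule",
    "SyntheticTruth",
    "generate_cohort",
    "generate_gene_sets",
    "generate_candidate_lists",
]

_DISORDERS = ("AUT", "SCZ", "BPD")


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.

    Default group sizes mirror a two-source cortical cohort: 47 AUT cases
    with 57 batch-I controls, 31 SCZ and 25 BPD cases sharing 26 batch-II
    controls.  The gene count defaults to 2,000 (a desk-scale stand-in for a
    filtered protein-coding transcriptome).
    """

    n_genes: int = 2000
    n_aut: int = 47
    n_scz: int = 31
    n_bpd: int = 25
    n_controls_batch1: int = 57
    n_controls_batch2: int = 26

    # co-expression structure; module_disease_shift > 0 adds that mean shift
    # to a module's factor in the cases of its assigned disorder combination
    # (combinations cycle through a fixed pattern), so eigengenes associate
    # with disease status
    n_modules: int = 5
    module_size: int = 30
    factor_sd: float = 1.0
    loading_range: tuple[float, float] = (0.5, 1.0)
    module_disease_shift: float = 0.0

    # planted aberrant gene sets (per disorder); shared_set_combos lists
    # disorder combinations that each get ONE additional set dispersed in
    # every listed disorder's cases (the cross-disorder signal the shared-set
    # clustering stage detects)
    sets_per_disorder: int = 3
    set_size: int = 20
    tau: float = 2.0
    rho: float = 1.0
    shared_set_combos: tuple = ()
    # draw shared sets' genes from planted module gene pools so the two
    # method families (dispersion screen, consensus modules) overlap
    shared_sets_overlap_modules: bool = False

    # nuisance structure
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    batch_sd: float = 0.5
    age_effect_sd: float = 0.01
    sex_effect_sd: float = 0.2
    region_effect_sd: float = 0.3
    n_hidden: int = 3
    hidden_loading_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_aut", "n_scz", "n_bpd",
                     "n_controls_batch1", "n_controls_batch2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module genes exceed the gene universe")
        for combo in self.shared_set_combos:
            if not set(combo) <= set(_DISORDERS):
                raise ValueError(f"unknown disorder(s) in combo {combo}")
        if self.shared_sets_overlap_modules:
            if self.n_modules == 0:
                raise ValueError("shared_sets_overlap_modules needs modules")
            if self.set_size > self.module_size:
                raise ValueError("set_size must not exceed module_size when "
                                 "shared sets are drawn from modules")
        needed = (self.n_modules * self.module_size
                  + (3 * self.sets_per_disorder + len(self.shared_set_combos))
                  * self.set_size)
        if needed > self.n_genes:
            raise ValueError(
                f"planted structure needs {needed} genes but universe has "
                f"{self.n_genes}"
            )


@dataclass(frozen=True)
class PlantedSet:
    """A planted aberrant gene set.  ``disorder`` is a single disorder name
    or a '+'-joined combination for sets dispersed in several disorders."""

    name: str
    disorder: str
    genes: tuple
    tau: float
    rho: float
    affected_cases: tuple

    @property
    def disorders(self) -> tuple:
        return tuple(self.disorder.split("+"))


@dataclass(frozen=True)
class PlantedModule:
    name: str
    genes: tuple
    disorders: tuple = ()   # disorders whose cases shift this module's factor


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    seed: int
    planted_aberrant_sets: list[PlantedSet]
    planted_modules: list[PlantedModule]
    module_factors: pd.DataFrame = field(repr=False)  # modules x samples
    batch_offset_sd: float = 0.0

    def sets_for(self, disorder: str) -> list[PlantedSet]:
        return [s for s in self.planted_aberrant_sets
                if disorder in s.disorders]

    def module_labels(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Truth module label per gene (0 = background), aligned to gene_ids."""
        lab = {g: i + 1 for i, m in enumerate(self.planted_modules) for g in m.genes}
        return np.array([lab.get(g, 0) for g in gene_ids])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_aberrant_sets": [asdict(s) for s in self.planted_aberrant_sets],
            "planted_modules": [asdict(m) for m in self.planted_modules],
        }


def _sample_frame(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    regions_b1 = ("BA19", "BA10", "BA44")

    def add(prefix, n, diagnosis, batch):
        for i in range(n):
            if batch == "I":
                region = regions_b1[int(rng.integers(len(regions_b1)))]
            else:
                region = "BA24"
            rows.append({
                "sample_id": f"{prefix}{i + 1:03d}",
                "diagnosis": diagnosis,
                "age": float(np.round(rng.uniform(20, 70), 1)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "brain_region": region,
                "source_batch": batch,
            })

    add("AUT", cfg.n_aut, "AUT", "I")
    add("CTL1_", cfg.n_controls_batch1, "control", "I")
    add("SCZ", cfg.n_scz, "SCZ", "II")
    add("BPD", cfg.n_bpd, "BPD", "II")
    add("CTL2_", cfg.n_controls_batch2, "control", "II")
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort.

    Returns ``(expression, samples, truth)`` where ``expression`` is a
    genes x samples DataFrame of log-scale values, ``samples`` the phenotype
    table, and ``truth`` the planted structure.

    The generative model per gene g and sample s is

        x_gs = mu_g + sum_m lambda_gm f_ms + batch_g,b(s)
               + beta_age,g age_s + beta_sex,g sex_s + beta_region,g,r(s)
               + sum_k gamma_gk h_ks + eps_gs

    with eps_gs ~ N(0, sigma_g^2); for an *affected* case of a planted
    aberrant set, eps on member genes is drawn with SD tau * sigma_g.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    (ss_samples, ss_genes, ss_modules, ss_sets,
     ss_covar, ss_hidden, ss_noise) = [np.random.default_rng(s) for s in ss.spawn(7)]

    samples = _sample_frame(cfg, ss_samples)
    n_s = len(samples)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    mu = ss_genes.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    sigma = ss_genes.uniform(0.8, 1.2, size=cfg.n_genes) * cfg.noise_sd

    # --- planted modules (disjoint gene blocks, positive loadings) ----------
    perm = ss_genes.permutation(cfg.n_genes)
    cursor = 0
    modules: list[PlantedModule] = []
    module_gene_idx: list[np.ndarray] = []
    loadings = np.zeros((cfg.n_genes, cfg.n_modules))
    factors = ss_modules.normal(0.0, cfg.factor_sd, size=(cfg.n_modules, n_s))
    diag_all = samples["diagnosis"].to_numpy()
    shift_pattern = (("AUT", "SCZ", "BPD"), ("AUT", "SCZ"), ("SCZ", "BPD"),
                     ("AUT", "BPD"), ("AUT",), ("SCZ",), ("BPD",))
    for m in range(cfg.n_modules):
        idx = perm[cursor:cursor + cfg.module_size]
        cursor += cfg.module_size
        lo, hi = cfg.loading_range
        loadings[idx, m] = ss_modules.uniform(lo, hi, size=len(idx))
        assigned: tuple = ()
        if cfg.module_disease_shift > 0:
            assigned = shift_pattern[m % len(shift_pattern)]
            for d in assigned:
                factors[m, diag_all == d] += cfg.module_disease_shift
        module_gene_idx.append(np.sort(idx))
        modules.append(PlantedModule(
            name=f"MODULE_{m + 1}",
            genes=tuple(gene_ids[i] for i in sorted(idx)),
            disorders=assigned,
        ))

    # --- planted aberrant sets (from the non-module remainder) -------------
    planted: list[PlantedSet] = []
    diag = samples["diagnosis"].to_numpy()

    def affected_for(disorders):
        picks = []
        for d in disorders:
            case_ids = samples.index[diag == d].to_numpy()
            n_aff = max(1, int(round(cfg.rho * len(case_ids))))
            picks.extend(ss_sets.choice(case_ids, size=n_aff, replace=False))
        return tuple(sorted(picks))

    for d in _DISORDERS:
        for k in range(cfg.sets_per_disorder):
            idx = perm[cursor:cursor + cfg.set_size]
            cursor += cfg.set_size
            planted.append(PlantedSet(
                name=f"PLANTED_{d}_{k + 1}",
                disorder=d,
                genes=tuple(gene_ids[i] for i in sorted(idx)),
                tau=cfg.tau,
                rho=cfg.rho,
                affected_cases=affected_for((d,)),
            ))
    for k, combo in enumerate(cfg.shared_set_combos):
        if cfg.shared_sets_overlap_modules:
            pool = module_gene_idx[k % cfg.n_modules]
            idx = ss_sets.choice(pool, size=cfg.set_size, replace=False)
        else:
            idx = perm[cursor:cursor + cfg.set_size]
            cursor += cfg.set_size
        planted.append(PlantedSet(
            name=f"PLANTED_SHARED_{k + 1}",
            disorder="+".join(combo),
            genes=tuple(gene_ids[i] for i in sorted(idx)),
            tau=cfg.tau,
            rho=cfg.rho,
            affected_cases=affected_for(combo),
        ))

    # --- nuisance terms -----------------------------------------------------
    batch_offset = ss_covar.normal(0.0, cfg.batch_sd, size=cfg.n_genes)
    is_b2 = (samples["source_batch"] == "II").to_numpy(dtype=float)

    beta_age = ss_covar.normal(0.0, cfg.age_effect_sd, size=cfg.n_genes)
    beta_sex = ss_covar.normal(0.0, cfg.sex_effect_sd, size=cfg.n_genes)
    regions = sorted(samples["brain_region"].unique())
    beta_region = ss_covar.normal(0.0, cfg.region_effect_sd,
                                  size=(cfg.n_genes, len(regions)))
    region_idx = samples["brain_region"].map({r: i for i, r in enumerate(regions)})
    age = samples["age"].to_numpy()
    sex = (samples["sex"] == "M").to_numpy(dtype=float)

    hidden = ss_hidden.normal(size=(cfg.n_hidden, n_s))
    gamma = ss_hidden.normal(0.0, cfg.hidden_loading_sd,
                             size=(cfg.n_genes, cfg.n_hidden))

    # --- assemble -----------------------------------------------------------
    x = mu[:, None] + loadings @ factors
    x += batch_offset[:, None] * is_b2[None, :]
    x += beta_age[:, None] * (age - age.mean())[None, :]
    x += beta_sex[:, None] * sex[None, :]
    x += beta_region[:, region_idx.to_numpy()]
    x += gamma @ hidden

    noise = ss_noise.normal(size=(cfg.n_genes, n_s)) * sigma[:, None]
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    col = {s: j for j, s in enumerate(samples.index)}
    for ps in planted:
        rows = [gene_row[g] for g in ps.genes]
        cols = [col[s] for s in ps.affected_cases]
        noise[np.ix_(rows, cols)] *= ps.tau
    x += noise

    expression = pd.DataFrame(x, index=gene_ids, columns=samples.index)
    truth = SyntheticTruth(
        seed=seed,
        planted_aberrant_sets=planted,
        planted_modules=modules,
        module_factors=pd.DataFrame(factors,
                                    index=[m.name for m in modules],
                                    columns=samples.index),
        batch_offset_sd=cfg.batch_sd,
    )
    return expression, samples, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    universe: Sequence[str],
    n_decoys: int = 200,
    size_range: tuple[int, int] = (10, 40),
    overlap_pairs: int = 0,
    seed: int = 0,
) -> GeneSetCollection:
    """A GMT-style collection: the planted sets under their true names, plus
    uniformly drawn decoy sets, plus optional near-duplicate pairs
    (Jaccard distance < 0.3 by construction) to exercise set clustering."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    universe = list(universe)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("size_range exceeds the gene universe")
    sets: list[GeneSet] = []
    for ps in truth.planted_aberrant_sets:
        missing = set(ps.genes) - set(universe)
        if missing:
            raise ValueError(f"planted set {ps.name} has genes outside the universe")
        sets.append(GeneSet(ps.name, f"planted {ps.disorder} tau={ps.tau}",
                            frozenset(ps.genes), total_count=len(ps.genes)))
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"DECOY_{i + 1:04d}", "decoy",
                            frozenset(members), total_count=size))
    for i in range(overlap_pairs):
        size = max(int(rng.integers(max(lo, 8), hi + 1)), 8)
        base = list(rng.choice(universe, size=size, replace=False))
        # replacing r of s members gives Jaccard distance 2r/(s+r) < 0.3
        r = max(1, int(0.15 * size))
        pool = [g for g in universe if g not in base]
        partner = base[:-r] + list(rng.choice(pool, size=r, replace=False))
        sets.append(GeneSet(f"TWIN_{i + 1:02d}A", "near-duplicate pair",
                            frozenset(base), total_count=size))
        sets.append(GeneSet(f"TWIN_{i + 1:02d}B", "near-duplicate pair",
                            frozenset(partner), total_count=len(set(partner))))
    return GeneSetCollection(sets)


def generate_candidate_lists(
    truth: SyntheticTruth,
    universe: Sequence[str],
    enrichment_factor: float = 10.0,
    n_candidates: int = 200,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Per-disorder candidate-gene lists.

    Members of that disorder's planted sets are oversampled by
    ``enrichment_factor`` relative to the background rate; with factor 1 the
    lists are uniform draws (a null for the enrichment test).
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    universe = np.asarray(list(universe))
    out: dict[str, list[str]] = {}
    for d in _DISORDERS:
        planted_genes = {g for s in truth.sets_for(d) for g in s.genes}
        w = np.ones(len(universe))
        w[np.isin(universe, list(planted_genes))] = enrichment_factor
        w /= w.sum()
        n = min(n_candidates, len(universe))
        picks = rng.choice(universe, size=n, replace=False, p=w)
        out[d] = sorted(picks.tolist())
    return out
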