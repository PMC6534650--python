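"""Consensus signed co-expression networks across case/control datasets.

Per dataset: biweight midcorrelation between genes, signed soft-threshold
adjacency a_ij = ((1 + cor_ij)/2)^beta, and the topological overlap matrix
(TOM).  The per-dataset TOMs are quantile-scaled to the first dataset and
combined by elementwise minimum into a consensus TOM; modules are clusters
of the consensus dissimilarity 1 - TOM (average linkage, static cut,
minimum size rule).  Each module is summarized by its eigengene (first
principal component of the standardized module expression) and associated
with sample traits by Pearson correlation with BH-adjusted p-values.

The soft threshold defaults to beta = 5; `scale_free_fit` verifies the
approximate scale-free topology of an adjacency (signed R^2 of the
log-log degree-distribution regression) rather than picking beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .aberrance import bh_fdr

__all__ = [
    "ConsensusNetwork",
    "ModuleAssignment",
    "ModuleTraitResult",
    "bicor",
    "bicor_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "tom",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "sample_traits",
    "module_trait_association",
    "consensus_modules",
    "control_split_robustness",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation and adjacency


def _bicor_normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight midcorrelation transform.

    Each row is median-centered, weighted by (1-u^2)^2 for u = dev/(9*MAD)
    (zero weight for |u| >= 1) and scaled to unit norm.  Rows with MAD = 0
    fall back to the Pearson transform (mean-centered, unit norm); the
    returned mask flags them.  The bicor of two rows is then just the dot
    product of their transforms."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
        w = np.square(1.0 - u ** 2) * (np.abs(u) < 1)
        xt = np.nan_to_num(dev * w)
    if fallback.any():
        Xf = X[fallback]
        xt[fallback] = Xf - Xf.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xt, axis=1, keepdims=True)
    zero = norm[:, 0] == 0
    if zero.any():
        raise ValueError("constant vector: bicor undefined even with "
                         "Pearson fallback")
    return xt / norm, fallback


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (length >= 3).

    Median/MAD-based and therefore robust to outliers; a vector with zero
    MAD falls back to its Pearson transform (logged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    t, fb = _bicor_normalize(np.vstack([x, y]))
    if fb.any():
        log.info("bicor: MAD = 0 for %d input(s); Pearson fallback", fb.sum())
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(X) -> np.ndarray:
    """Gene x gene biweight midcorrelation for a genes x samples matrix."""
    X = np.asarray(X, dtype=float)
    t, fb = _bicor_normalize(X)
    if fb.any():
        log.info("bicor_matrix: Pearson fallback for %d gene(s)", fb.sum())
    C = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def signed_adjacency(correlations: np.ndarray, beta: int = 5) -> np.ndarray:
    """a_ij = ((1 + cor_ij)/2)^beta with unit diagonal.

    The signed map keeps negative correlations near zero adjacency, so
    modules of anti-correlated genes do not merge."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = np.asarray(correlations, dtype=float)
    if np.any(C < -1 - 1e-12) or np.any(C > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    A = ((1.0 + np.clip(C, -1, 1)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    Connectivity k_i = sum_{j != i} a_ij is discretized into ``n_bins``
    equal-width bins; R^2 of the regression of log10(frequency) on
    log10(mean k) over nonempty bins, negated when the slope is positive
    (only decreasing degree distributions count as scale-free).  Equal-width
    binning is what makes the bin frequencies informative: with equal-count
    bins every frequency would be identical and the fit degenerate."""
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    if n < 50:
        raise ValueError("need at least 50 genes for a degree-distribution fit")
    k = A.sum(axis=1) - np.diag(A)
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities equal: scale-free fit undefined")
    cuts = pd.cut(k, bins=n_bins, duplicates="drop")
    df = pd.DataFrame({"k": k, "bin": cuts})
    g = df.groupby("bin", observed=True)["k"]
    mean_k = g.mean().to_numpy()
    freq = g.size().to_numpy() / n
    ok = (mean_k > 0) & (freq > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable bins for the scale-free fit")
    fit = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    r2 = fit.rvalue ** 2
    return float(-r2 if fit.slope > 0 else r2)


# ---------------------------------------------------------------------------
# topological overlap and the consensus


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with TOM_ii = 1; combines the direct edge with shared-neighbor support."""
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0                      # (A0^2)_ij = sum_{u != i,j} a_iu a_uj
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A0) / denom
    T = np.nan_to_num(T, nan=0.0)
    T = np.clip(T, 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    return T


def consensus_tom(tom_list, q: float = 0.95) -> np.ndarray:
    """Elementwise-minimum consensus of quantile-scaled TOMs.

    Each TOM is scaled multiplicatively so that the ``q``-quantile of its
    off-diagonal entries matches that of the first TOM (removing
    dataset-specific overall connectivity differences), then the consensus
    is the elementwise minimum, clipped to [0, 1]."""
    toms = [np.asarray(t, dtype=float) for t in tom_list]
    if len(toms) < 2:
        raise ValueError("need at least 2 TOMs")
    shape = toms[0].shape
    if any(t.shape != shape for t in toms):
        raise ValueError("TOM shape mismatch")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    off = ~np.eye(shape[0], dtype=bool)
    ref = np.quantile(toms[0][off], q)
    scaled = []
    for t in toms:
        qt = np.quantile(t[off], q)
        s = t * (ref / qt) if qt > 0 else t
        scaled.append(s)
    cons = np.minimum.reduce(scaled)
    cons = np.clip(cons, 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return cons


# ---------------------------------------------------------------------------
# modules


@dataclass
class ModuleAssignment:
    labels: np.ndarray           # per gene; 0 = unassigned
    gene_ids: list
    linkage: np.ndarray = field(repr=False)

    @property
    def module_sizes(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def genes_of(self, module: int) -> list:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module]

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


def detect_modules(
    consensus: np.ndarray,
    min_size: int = 20,
    cut_height: float = 0.85,
    gene_ids=None,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` are unassigned (label 0); labels are
    renumbered by decreasing module size (ties broken by first gene)."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    T = np.asarray(consensus, dtype=float)
    n = T.shape[0]
    gene_ids = list(gene_ids) if gene_ids is not None else list(range(n))
    dis = 1.0 - T
    np.fill_diagonal(dis, 0.0)
    dis = np.maximum((dis + dis.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(dis, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = []
    for cid in np.unique(raw):
        idx = np.flatnonzero(raw == cid)
        if len(idx) >= min_size:
            sizes.append((len(idx), int(idx[0]), idx))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for new_id, (_, _, idx) in enumerate(sizes, start=1):
        labels[idx] = new_id
    return ModuleAssignment(labels=labels, gene_ids=gene_ids, linkage=Z)


def module_eigengene(expr) -> np.ndarray:
    """Module eigengene: first principal component over samples.

    ``expr`` is the module's genes x samples matrix.  Genes are
    standardized, the first right-singular vector is taken, sign-aligned so
    its correlation with the module's mean expression profile is >= 0, and
    returned with unit norm.  Zero-variance genes are dropped (warned)."""
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("module_eigengene: dropping %d zero-variance gene(s)",
                    int((~keep).sum()))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes in the module")
    Xk = X[keep]
    Z = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return e / np.linalg.norm(e)


def sample_traits(samples: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait frame for eigengene association: age, sex (0/1
    indicator for male) and one 0/1 indicator per disorder present."""
    out = pd.DataFrame(index=samples.index)
    if "age" in samples.columns:
        out["age"] = samples["age"].astype(float)
    if "sex" in samples.columns:
        out["sex_M"] = (samples["sex"] == "M").astype(float)
    if "diagnosis" in samples.columns:
        for d in ("AUT", "SCZ", "BPD"):
            if (samples["diagnosis"] == d).any():
                out[f"diagnosis_{d}"] = (samples["diagnosis"] == d).astype(float)
    return out


@dataclass
class ModuleTraitResult:
    eigengenes: pd.DataFrame     # modules x samples
    table: pd.DataFrame          # module, trait, r, p, q, significant
    shared_modules: list         # significant for >= 2 disease indicators


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    fdr_cut: float = 0.1,
    disease_traits=None,
) -> ModuleTraitResult:
    """Pearson correlation of each module eigengene with each trait.

    ``traits`` is samples x traits, numeric (binary traits coded 0/1),
    aligned to the eigengene columns.  BH correction runs across all
    defined (module, trait) pairs; constant traits are reported with
    undefined r/p and excluded from the correction.  A module is *shared*
    when significant (q < ``fdr_cut``) for at least two of the
    ``disease_traits`` (default: traits named like diagnosis indicators)."""
    if list(traits.index) != list(eigengenes.columns):
        raise ValueError("traits must be aligned to the eigengene samples")
    if disease_traits is None:
        disease_traits = [c for c in traits.columns
                          if c.split("_")[-1] in ("AUT", "SCZ", "BPD")]
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if np.std(t) == 0 or np.std(e) == 0:
                rows.append({"module": module, "trait": trait,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(e, t)
            rows.append({"module": module, "trait": trait,
                         "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    defined = table["p"].notna()
    table["q"] = np.nan
    if defined.any():
        table.loc[defined, "q"] = bh_fdr(table.loc[defined, "p"].to_numpy())
    table["significant"] = table["q"] < fdr_cut

    shared = []
    for module in eigengenes.index:
        hits = table[(table["module"] == module)
                     & table["trait"].isin(disease_traits)
                     & table["significant"]]
        if len(hits) >= 2:
            shared.append(module)
    return ModuleTraitResult(eigengenes=eigengenes, table=table,
                             shared_modules=shared)


# ---------------------------------------------------------------------------
# pipeline and robustness


@dataclass
class ConsensusNetwork:
    beta: int
    q: float
    toms: list = field(repr=False)           # per-dataset TOMs
    consensus: np.ndarray = field(repr=False)
    scale_free_r2: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)


def build_consensus_network(
    datasets,
    beta: int = 5,
    q: float = 0.95,
    gene_ids=None,
    with_fit: bool = False,
) -> ConsensusNetwork:
    """bicor -> signed adjacency -> TOM per dataset, then consensus TOM.

    ``datasets`` is a list of genes x samples matrices (identical gene
    order)."""
    mats = [np.asarray(d, dtype=float) for d in datasets]
    if len(mats) < 2:
        raise ValueError("need at least 2 datasets")
    n_genes = mats[0].shape[0]
    if any(m.shape[0] != n_genes for m in mats):
        raise ValueError("datasets must share the gene universe")
    toms, fits = [], []
    for m in mats:
        A = signed_adjacency(bicor_matrix(m), beta=beta)
        if with_fit:
            fits.append(scale_free_fit(A))
        toms.append(tom(A))
    cons = consensus_tom(toms, q=q)
    if gene_ids is None:
        gene_ids = list(range(n_genes))
    return ConsensusNetwork(beta=beta, q=q, toms=toms, consensus=cons,
                            scale_free_r2=fits, gene_ids=list(gene_ids))


def consensus_modules(
    datasets,
    beta: int = 5,
    q: float = 0.95,
    min_size: int = 20,
    cut_height: float = 0.85,
    gene_ids=None,
) -> tuple[ModuleAssignment, ConsensusNetwork]:
    """End-to-end consensus module detection on aligned datasets."""
    net = build_consensus_network(datasets, beta=beta, q=q, gene_ids=gene_ids)
    assignment = detect_modules(net.consensus, min_size=min_size,
                                cut_height=cut_height, gene_ids=net.gene_ids)
    return assignment, net


def _co_cluster_fraction(full_idx: np.ndarray, rep_labels: np.ndarray) -> float:
    """Fraction of the module's gene pairs (by full-data assignment) that
    co-cluster in a rep's assignment (pairs with an unassigned gene count
    as split)."""
    m = len(full_idx)
    total = m * (m - 1) // 2
    if total == 0:
        return float("nan")
    sub = rep_labels[full_idx]
    together = 0
    for lab, cnt in zip(*np.unique(sub[sub > 0], return_counts=True)):
        together += cnt * (cnt - 1) // 2
    return together / total


@dataclass
class RobustnessResult:
    full_assignment: ModuleAssignment
    stability: pd.DataFrame      # module x rep co-cluster fractions
    median_stability: pd.Series  # per module

    @property
    def overall_median(self) -> float:
        vals = self.stability.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else 1.0


def control_split_robustness(
    bundles: dict,
    reps: int = 100,
    seed: int = 0,
    beta: int = 5,
    q: float = 0.95,
    min_size: int = 20,
    cut_height: float = 0.85,
) -> RobustnessResult:
    """Stability of the consensus modules under random splits of the
    controls shared between two datasets.

    The per-disorder bundles whose control samples overlap are identified;
    per rep their shared controls are split into disjoint halves (seeded),
    one half joining each of the two datasets, and the consensus modules
    are rebuilt with identical parameters.  Stability of a full-data module
    in a rep is the fraction of its gene pairs still co-clustered.  With no
    shared controls the full-data assignment is returned with stability 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = list(bundles)
    gene_ids = list(bundles[names[0]].expression.index)
    datasets = [bundles[d].expression.to_numpy(dtype=float) for d in names]
    full, _ = consensus_modules(datasets, beta=beta, q=q, min_size=min_size,
                                cut_height=cut_height, gene_ids=gene_ids)

    ctl_ids = {d: set(b.samples.index[b.samples["diagnosis"] == "control"])
               for d, b in bundles.items()}
    pair = None
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if ctl_ids[a] & ctl_ids[b]:
                pair = (a, b)
                break
        if pair:
            break
    modules = sorted(full.module_sizes)
    if pair is None:
        stab = pd.DataFrame(1.0, index=modules, columns=["rep1"])
        return RobustnessResult(full_assignment=full, stability=stab,
                                median_stability=stab.median(axis=1))

    a, b = pair
    shared = sorted(ctl_ids[a] & ctl_ids[b])
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared controls; need >= 4")
    module_idx = {m: np.flatnonzero(full.labels == m) for m in modules}
    ss = np.random.SeedSequence(seed)
    cols = {}
    for r, child in enumerate(ss.spawn(reps), start=1):
        rng = np.random.default_rng(child)
        perm = rng.permutation(shared)
        half_a = set(perm[: len(shared) // 2])
        half_b = set(perm[len(shared) // 2:])
        rep_sets = []
        for d in names:
            bun = bundles[d]
            keep = []
            for s in bun.samples.index:
                if s in ctl_ids[a] & ctl_ids[b]:
                    if d == a and s not in half_a:
                        continue
                    if d == b and s not in half_b:
                        continue
                keep.append(s)
            rep_sets.append(bun.expression.loc[:, keep].to_numpy(dtype=float))
        rep_assign, _ = consensus_modules(rep_sets, beta=beta, q=q,
                                          min_size=min_size,
                                          cut_height=cut_height,
                                          gene_ids=gene_ids)
        cols[f"rep{r}"] = {
            m: _co_cluster_fraction(module_idx[m], rep_assign.labels)
            for m in modules
        }
    stab = pd.DataFrame(cols)
    return RobustnessResult(full_assignment=full, stability=stab,
                            median_stability=stab.median(axis=1))
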