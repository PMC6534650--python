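"""Dispersion-based multivariate screen for aberrantly expressed gene sets.

For one gene set with p genes, the location and scatter of the control
samples are estimated robustly with the Minimum Covariance Determinant
(MCD): among all subsets of h = floor(alpha * n) controls, the one whose
sample covariance has the smallest determinant provides the location
(mean) and scatter (covariance, denominator h-1).  Each case sample i then
gets a robust Mahalanobis distance

    MD_i = sqrt((x_i - y_c)^T psi_c^{-1} (x_i - y_c))

and the gene set's statistic is the sum of squared distances over the m
cases, SSMD = sum_i MD_i^2 — the overall dispersion of cases around the
robust control centroid.  Significance comes from a permutation null: N
random gene sets of identical size are drawn from the analyzed-gene
universe, the whole MCD + SSMD computation is re-run for each, and
P_perm = M/N where M counts null SSMD values strictly greater than the
observed one.  Benjamini-Hochberg adjustment is applied across sets, and a
leave-one-gene-out decomposition (delta SSMD) ranks the genes inside a
significant set.

The raw h-subset MCD estimates are used as-is: no reweighting step and no
consistency correction, so the statistic is exactly the plain subset mean
and covariance of the determinant-minimizing h controls.

The FAST-MCD search here is batched: C-steps for many random starts (and,
in the permutation test, many random gene sets at once) are advanced with
stacked linear algebra, which is what makes thousands of per-set
permutations tractable on one CPU.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg as sla
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RobustCenter",
    "AberranceResult",
    "ScreenResult",
    "PermutationResult",
    "SetTooLargeError",
    "SingularScatterError",
    "mcd_location_scatter",
    "exhaustive_mcd",
    "mahalanobis",
    "ssmd",
    "permutation_test",
    "bh_fdr",
    "delta_ssmd",
    "run_screen",
    "subsample_case_screen",
]

log = logging.getLogger(__name__)


class SetTooLargeError(ValueError):
    """Gene set dimension p is not below the MCD subset size h."""

    def __init__(self, p: int, h: int):
        self.p, self.h = p, h
        super().__init__(f"set too large for MCD: p={p} genes but h={h} controls")


class SingularScatterError(ValueError):
    """The h-subset covariance is singular (e.g. a zero-variance gene)."""


@dataclass
class RobustCenter:
    """MCD location/scatter of the controls for one gene set."""

    location: np.ndarray          # (p,)
    scatter: np.ndarray           # (p, p), denominator h-1
    h_subset: np.ndarray          # indices of the h controls used
    h: int
    n: int

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if self.scatter.shape != (self.location.size,) * 2:
            raise ValueError("scatter shape does not match location")
        try:
            self._chol = sla.cho_factor(self.scatter, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularScatterError(str(exc)) from exc

    @property
    def p(self) -> int:
        return self.location.size


# ---------------------------------------------------------------------------
# batched FAST-MCD


def _safe_inv_logdet(covs: np.ndarray, ridge_tries: int = 3):
    """Batched inverse + log-determinant with a tiny-ridge rescue for
    numerically singular matrices.  Matrices that stay singular are flagged
    dead (logdet = +inf) and replaced by the identity so batch shapes hold."""
    covs = covs.copy()
    p = covs.shape[-1]
    eye = np.eye(p)
    sign, logdet = np.linalg.slogdet(covs)
    bad = (sign <= 0) | ~np.isfinite(logdet)
    tries = 0
    while bad.any() and tries < ridge_tries:
        tr = np.trace(covs[bad], axis1=-2, axis2=-1)
        lam = np.maximum(tr / p, 1.0) * 1e-10 * (10.0 ** tries)
        covs[bad] += lam[:, None, None] * eye
        sign_b, logdet_b = np.linalg.slogdet(covs[bad])
        sign[bad], logdet[bad] = sign_b, logdet_b
        bad = (sign <= 0) | ~np.isfinite(logdet)
        tries += 1
    dead = bad
    if dead.any():
        covs[dead] = eye
        logdet = logdet.copy()
        logdet[dead] = np.inf
    inv = np.linalg.inv(covs)
    return inv, logdet, dead


def _subset_moments(Xb: np.ndarray, idx: np.ndarray):
    """Mean and (m-1)-denominator covariance of the indexed rows.

    Xb: (G, n, p); idx: (G, m) row indices per batch element."""
    G = Xb.shape[0]
    pts = Xb[np.arange(G)[:, None], idx]          # (G, m, p)
    loc = pts.mean(axis=1)
    c = pts - loc[:, None, :]
    m = idx.shape[1]
    cov = np.einsum("gmi,gmj->gij", c, c) / (m - 1)
    return loc, cov


def _c_steps(Xb, loc, cov, h, max_iters, tol=1e-10):
    """Run concentration steps for a stack of estimates.

    Returns (best_loc, best_cov, best_logdet, best_idx) per batch element.
    C-steps never increase the determinant, so tracking the best visited
    h-subset estimate and stopping when nothing improves is exact."""
    G, n, p = Xb.shape
    best_logdet = np.full(G, np.inf)
    best_loc = loc.copy()
    best_cov = cov.copy()
    best_idx = np.zeros((G, h), dtype=np.intp)
    # the incoming (loc, cov) only seeds the first concentration; bests are
    # tracked over h-subset estimates exclusively.  Estimates whose
    # determinant stops decreasing have converged (C-steps are monotone)
    # and are dropped from the batch.
    act = np.arange(G)
    inv, _, _ = _safe_inv_logdet(cov)
    for _ in range(max_iters):
        Xa = Xb[act]
        diff = Xa - loc[:, None, :]
        d2 = np.einsum("gip,gpq,giq->gi", diff, inv, diff)
        cur_idx = np.argpartition(d2, h - 1, axis=1)[:, :h]
        loc, cov = _subset_moments(Xa, cur_idx)
        inv, logdet, _ = _safe_inv_logdet(cov)
        improved = logdet < best_logdet[act] - tol
        if not improved.any():
            break
        g = act[improved]
        best_logdet[g] = logdet[improved]
        best_loc[g] = loc[improved]
        best_cov[g] = cov[improved]
        best_idx[g] = cur_idx[improved]
        act = g
        loc, cov, inv = loc[improved], cov[improved], inv[improved]
    return best_loc, best_cov, best_logdet, best_idx


def _fast_mcd_batch(
    Xs: np.ndarray,
    h: int,
    rng: np.random.Generator,
    n_starts: int = 10,
    keep: int = 3,
    phase1_iters: int = 3,
    max_iters: int = 50,
):
    """FAST-MCD for a stack of instances Xs (B, n, p).

    Classic scheme, batched: many random (p+1)-point starts per instance, a
    few concentration steps for all of them, then the best ``keep`` starts
    per instance are iterated to convergence.  Returns
    (loc (B,p), cov (B,p,p), logdet (B,), h_idx (B,h), dead (B,))."""
    B, n, p = Xs.shape
    if h >= n:  # classical estimate: the single h = n subset
        idx = np.tile(np.arange(n), (B, 1))
        loc, cov = _subset_moments(Xs, idx)
        _, logdet, dead = _safe_inv_logdet(cov)
        return loc, cov, logdet, idx, dead

    if n <= 20:
        # tiny problems: many more starts are nearly free and make the
        # search reliably exact (checked against exhaustive enumeration)
        n_starts = max(n_starts, 100)
        keep = max(keep, 5)
    S = n_starts
    b_of = np.repeat(np.arange(B), S)
    # random (p+1)-point starting subsets
    init = np.argpartition(rng.random((B * S, n)), p, axis=1)[:, : p + 1]
    Xb = Xs[b_of]
    loc, cov = _subset_moments(Xb, init)
    loc, cov, logdet, idx = _c_steps(Xb, loc, cov, h, phase1_iters)

    keep = min(keep, S)
    order = np.argsort(logdet.reshape(B, S), axis=1)[:, :keep]
    flat = (np.arange(B)[:, None] * S + order).ravel()
    b_of2 = np.repeat(np.arange(B), keep)
    loc2, cov2, logdet2, idx2 = _c_steps(
        Xs[b_of2], loc[flat], cov[flat], h, max_iters
    )
    pick = np.argmin(logdet2.reshape(B, keep), axis=1)
    sel = np.arange(B) * keep + pick
    loc_f, cov_f, logdet_f, idx_f = loc2[sel], cov2[sel], logdet2[sel], idx2[sel]
    dead = ~np.isfinite(logdet_f)
    return loc_f, cov_f, logdet_f, np.sort(idx_f, axis=1), dead


def mcd_location_scatter(
    controls: np.ndarray,
    alpha: float = 0.8,
    n_starts: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> RobustCenter:
    """Robust location/scatter of the controls for one gene set.

    ``controls`` is a p x n matrix (genes x control samples).  Requires
    h = floor(alpha * n) > p, otherwise every h-subset covariance is
    singular and the set is rejected (:class:`SetTooLargeError`)."""
    X = np.asarray(controls, dtype=float)
    if X.ndim != 2:
        raise ValueError("controls must be a p x n matrix")
    if not np.isfinite(X).all():
        raise ValueError("controls contain non-finite values")
    p, n = X.shape
    h = math.floor(alpha * n)
    if h <= p:
        raise SetTooLargeError(p, h)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loc, cov, logdet, idx, dead = _fast_mcd_batch(
        X.T[None], h, rng, n_starts=n_starts
    )
    if dead[0]:
        raise SingularScatterError(
            "singular scatter in every candidate h-subset "
            "(zero-variance or collinear genes?)"
        )
    return RobustCenter(location=loc[0], scatter=cov[0], h_subset=idx[0], h=h, n=n)


def exhaustive_mcd(controls: np.ndarray, alpha: float = 0.8) -> RobustCenter:
    """Exact MCD by enumerating every h-subset (feasible only for small n);
    intended as an independent check of the stochastic search."""
    X = np.asarray(controls, dtype=float)
    p, n = X.shape
    h = math.floor(alpha * n)
    if h <= p:
        raise SetTooLargeError(p, h)
    best = None
    for combo in combinations(range(n), h):
        sub = X[:, combo]
        loc = sub.mean(axis=1)
        c = sub - loc[:, None]
        cov = (c @ c.T) / (h - 1)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        if best is None or logdet < best[0]:
            best = (logdet, loc, cov, np.array(combo))
    if best is None:
        raise SingularScatterError("every h-subset covariance is singular")
    _, loc, cov, idx = best
    return RobustCenter(location=loc, scatter=cov, h_subset=idx, h=h, n=n)


# ---------------------------------------------------------------------------
# distances and the SSMD statistic


def mahalanobis(x: np.ndarray, center: RobustCenter) -> float:
    """sqrt((x - y_c)^T psi_c^{-1} (x - y_c)) via a Cholesky solve."""
    x = np.asarray(x, dtype=float)
    if x.shape != center.location.shape:
        raise ValueError("dimension mismatch between x and the robust center")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input vector")
    d = x - center.location
    sol = sla.cho_solve(center._chol, d)
    return float(np.sqrt(d @ sol))


def ssmd(cases: np.ndarray, center: RobustCenter) -> tuple[float, np.ndarray]:
    """Sum of squared Mahalanobis distances of the m case samples
    (``cases`` is p x m) to the robust control centroid.  Returns
    ``(ssmd, md)`` with the per-case distances in case order."""
    C = np.asarray(cases, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != center.p:
        raise ValueError("cases and center dimension mismatch")
    if C.shape[1] < 1:
        raise ValueError("need at least one case")
    if not np.isfinite(C).all():
        raise ValueError("non-finite case values")
    D = C - center.location[:, None]
    sol = sla.cho_solve(center._chol, D)
    md2 = np.einsum("pm,pm->m", D, sol)
    md = np.sqrt(np.maximum(md2, 0.0))
    return float(md2.sum()), md


# ---------------------------------------------------------------------------
# permutation null over random gene sets


@dataclass
class PermutationResult:
    p_perm: float
    observed_ssmd: float
    md: np.ndarray
    null_ssmds: np.ndarray
    n_redraws: int


def _as_matrix(frame) -> tuple[np.ndarray, dict]:
    if isinstance(frame, pd.DataFrame):
        return frame.to_numpy(dtype=float), {g: i for i, g in enumerate(frame.index)}
    raise TypeError("expected a genes x samples DataFrame")


def _null_ssmds_for_sets(
    idx_sets: np.ndarray,
    C: np.ndarray,
    A: np.ndarray,
    h: int,
    rng: np.random.Generator,
    n_starts: int,
) -> tuple[np.ndarray, np.ndarray]:
    """SSMD of each random gene set (rows of ``idx_sets``) after a from-
    scratch MCD fit.  C, A: universe x samples arrays (controls, cases)."""
    Xs = C[idx_sets].transpose(0, 2, 1)     # (B, n_controls, p)
    loc, cov, _, _, dead = _fast_mcd_batch(Xs, h, rng, n_starts=n_starts)
    inv, _, dead2 = _safe_inv_logdet(cov)
    dead = dead | dead2
    diff = A[idx_sets] - loc[:, :, None]    # (B, p, m)
    vals = np.einsum("bpm,bpq,bqm->b", diff, inv, diff)
    return vals, dead


def permutation_test(
    set_genes,
    universe,
    controls: pd.DataFrame,
    cases: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.8,
    n_starts: int = 10,
    chunk: int = 256,
    max_redraw_factor: int = 10,
    mode: str = "plain",
) -> PermutationResult:
    """Permutation P-value of one gene set's SSMD.

    ``n_perm`` gene sets of identical size are drawn uniformly without
    replacement from ``universe`` (seeded); for each one the MCD and SSMD
    are recomputed from scratch on the same control/case samples.  Random
    sets with singular scatter are redrawn (logged); more than
    ``max_redraw_factor * n_perm`` redraws is an error.

    ``mode="plain"`` gives P = M/N with strict "greater than" (so P can be
    exactly 0); ``mode="add_one"`` gives (M+1)/(N+1).
    """
    set_genes = list(set_genes)
    universe = list(universe)
    p = len(set_genes)
    if p > len(universe):
        raise ValueError("gene set larger than the universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("plain", "add_one"):
        raise ValueError("mode must be 'plain' or 'add_one'")

    C_full, row = _as_matrix(controls)
    A_full, row_a = _as_matrix(cases)
    if row != row_a:
        raise ValueError("controls and cases must share the same gene index")
    missing = [g for g in set_genes if g not in row]
    if missing:
        raise KeyError(f"set gene(s) not in the expression data: {missing[:5]}")
    uni_idx = np.array([row[g] for g in universe])
    C = C_full[uni_idx]
    A = A_full[uni_idx]

    n = C.shape[1]
    h = math.floor(alpha * n)
    if h <= p:
        raise SetTooLargeError(p, h)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_obs, rng_draw, rng_fit = [np.random.default_rng(s) for s in ss.spawn(3)]

    set_idx = np.array([row[g] for g in set_genes])
    center = mcd_location_scatter(C_full[set_idx], alpha=alpha,
                                  n_starts=n_starts, seed=rng_obs)
    observed, md = ssmd(A_full[set_idx], center)

    G = len(universe)
    null_vals = np.empty(n_perm)
    filled = 0
    redraws = 0
    while filled < n_perm:
        want = min(chunk, n_perm - filled)
        draws = np.argpartition(rng_draw.random((want, G)), p - 1, axis=1)[:, :p]
        vals, dead = _null_ssmds_for_sets(draws, C, A, h, rng_fit, n_starts)
        ok = ~dead
        k = int(ok.sum())
        null_vals[filled:filled + k] = vals[ok]
        filled += k
        redraws += want - k
        if redraws > max_redraw_factor * n_perm:
            raise SingularScatterError(
                f"more than {max_redraw_factor}x{n_perm} singular random sets"
            )
    if redraws:
        log.info("permutation_test: %d random set(s) redrawn (singular scatter)",
                 redraws)

    M = int((null_vals > observed).sum())
    if mode == "plain":
        p_perm = M / n_perm
    else:
        p_perm = (M + 1) / (n_perm + 1)
    return PermutationResult(p_perm=p_perm, observed_ssmd=observed, md=md,
                             null_ssmds=null_vals, n_redraws=redraws)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# leave-one-gene-out decomposition


def delta_ssmd(
    set_genes,
    controls: pd.DataFrame,
    cases: pd.DataFrame,
    alpha: float = 0.8,
    n_starts: int = 10,
    seed: int = 0,
    center_fn=None,
) -> pd.DataFrame:
    """Per-gene contribution to a set's SSMD.

    For each gene j the full pipeline (robust center + SSMD) is re-run on
    the set minus gene j; delta_j = SSMD - SSMD_excluding_j.  Output is
    sorted by decreasing delta with the percentage 100*delta/SSMD (NaN when
    SSMD is 0).  delta values can be negative and the percentages need not
    sum to 100: removing a gene changes the whole covariance model, not
    just one additive term.

    ``center_fn(controls_submatrix, rng) -> RobustCenter`` overrides the
    default MCD estimator (used e.g. to check the decomposition against a
    fixed-scatter closed form).
    """
    set_genes = list(set_genes)
    if len(set_genes) < 2:
        raise ValueError("delta SSMD needs at least 2 genes")
    ss = np.random.SeedSequence(seed)

    def fit(genes, child):
        rng = np.random.default_rng(child)
        Cs = controls.loc[genes]
        As = cases.loc[genes]
        if center_fn is not None:
            center = center_fn(Cs.to_numpy(dtype=float), rng)
        else:
            center = mcd_location_scatter(Cs.to_numpy(dtype=float), alpha=alpha,
                                          n_starts=n_starts, seed=rng)
        return ssmd(As.to_numpy(dtype=float), center)[0]

    children = ss.spawn(len(set_genes) + 1)
    total = fit(set_genes, children[0])
    rows = []
    for j, g in enumerate(set_genes):
        reduced = [x for x in set_genes if x != g]
        val = fit(reduced, children[j + 1])
        delta = total - val
        pct = 100.0 * delta / total if total > 0 else np.nan
        rows.append({"gene": g, "delta_ssmd": delta, "pct_of_ssmd": pct})
    out = pd.DataFrame(rows).sort_values("delta_ssmd", ascending=False,
                                         kind="mergesort")
    out.attrs["ssmd"] = total
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# whole-collection screen


@dataclass
class AberranceResult:
    set_name: str
    p_genes: int
    label: str
    md: np.ndarray = field(repr=False)
    ssmd: float
    p_perm: float
    q_bh: float = np.nan
    delta: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ScreenResult:
    results: list
    table: pd.DataFrame
    significant: list
    skipped: list

    def __iter__(self):
        return iter(self.results)


def run_screen(
    bundle,
    coll,
    n_perm: int = 1000,
    seed: int = 0,
    p_cutoff: float = 0.01,
    alpha: float = 0.8,
    n_starts: int = 10,
    compute_delta: str = "significant",
    disorder: str | None = None,
) -> ScreenResult:
    """Score every eligible gene set of a per-disorder cohort.

    ``bundle`` is a :class:`~aberex.preprocess.CohortBundle` holding one
    disorder's cases and its controls; ``coll`` a
    :class:`~aberex.io_formats.GeneSetCollection` already restricted to the
    bundle's gene background.  Sets whose size is not below h are skipped
    with a logged warning.  ``compute_delta`` is one of "none",
    "significant", "all".
    """
    if compute_delta not in ("none", "significant", "all"):
        raise ValueError("compute_delta must be 'none', 'significant' or 'all'")
    diag = bundle.samples["diagnosis"]
    if disorder is None:
        non_control = sorted(set(diag) - {"control"})
        if len(non_control) != 1:
            raise ValueError(
                f"bundle holds {non_control}; pass disorder= to disambiguate"
            )
        disorder = non_control[0]
    controls = bundle.controls()
    cases = bundle.cases(disorder)
    if cases.shape[1] == 0:
        raise ValueError(f"no {disorder} cases in the bundle")
    universe = list(bundle.expression.index)
    n = controls.shape[1]
    h = math.floor(alpha * n)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(coll) + 1)
    results: list[AberranceResult] = []
    skipped: list[tuple[str, str]] = []
    for i, gs in enumerate(coll):
        genes = sorted(gs.members)
        if len(genes) >= h:
            log.warning("run_screen: skipping %s (p=%d >= h=%d)",
                        gs.name, len(genes), h)
            skipped.append((gs.name, f"p={len(genes)} >= h={h}"))
            continue
        try:
            perm = permutation_test(genes, universe, controls, cases,
                                    n_perm=n_perm, seed=children[i],
                                    alpha=alpha, n_starts=n_starts)
        except SingularScatterError as exc:
            skipped.append((gs.name, f"singular scatter: {exc}"))
            continue
        results.append(AberranceResult(
            set_name=gs.name, p_genes=len(genes), label=gs.label,
            md=perm.md, ssmd=perm.observed_ssmd, p_perm=perm.p_perm,
        ))

    if results:
        q = bh_fdr([r.p_perm for r in results])
        for r, qv in zip(results, q):
            r.q_bh = float(qv)
    significant = [r.set_name for r in results if r.p_perm <= p_cutoff]

    if compute_delta != "none":
        wanted = {r.set_name for r in results} if compute_delta == "all" \
            else set(significant)
        delta_children = ss.spawn(len(results))
        for r, child in zip(results, delta_children):
            if r.set_name in wanted and r.p_genes >= 2:
                genes = sorted(coll[r.set_name].members)
                r.delta = delta_ssmd(genes, controls, cases, alpha=alpha,
                                     n_starts=n_starts,
                                     seed=int(child.generate_state(1)[0] % (2**31)))

    table = pd.DataFrame([
        {"set": r.set_name, "included_total": r.label, "p_genes": r.p_genes,
         "ssmd": r.ssmd, "p_perm": r.p_perm, "q_bh": r.q_bh}
        for r in results
    ])
    return ScreenResult(results=results, table=table,
                        significant=significant, skipped=skipped)


@dataclass
class SubsampleResult:
    mean_count: float
    counts: list


def subsample_case_screen(
    bundle,
    coll,
    n_cases: int,
    reps: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    p_cutoff: float = 0.01,
    alpha: float = 0.8,
    n_starts: int = 10,
) -> SubsampleResult:
    """Significant-set counts when the screen is re-run on random case
    subsamples of fixed size (equalizing power across disorders).  Each rep
    draws ``n_cases`` cases without replacement, re-runs the screen on the
    same controls, and records the count of sets with P_perm <= cutoff."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    diag = bundle.samples["diagnosis"]
    case_ids = bundle.samples.index[diag != "control"].to_numpy()
    if n_cases > len(case_ids):
        raise ValueError(f"n_cases={n_cases} exceeds the {len(case_ids)} cases")
    ss = np.random.SeedSequence(seed)
    counts = []
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        chosen = set(rng.choice(case_ids, size=n_cases, replace=False))
        keep = (diag == "control") | bundle.samples.index.isin(chosen)
        sub = type(bundle)(
            expression=bundle.expression.loc[:, bundle.samples.index[keep]],
            samples=bundle.samples.loc[keep],
            provenance=list(bundle.provenance),
        )
        res = run_screen(sub, coll, n_perm=n_perm,
                         seed=int(child.generate_state(1)[0] % (2**31)),
                         p_cutoff=p_cutoff, alpha=alpha, n_starts=n_starts,
                         compute_delta="none")
        counts.append(len(res.significant))
    return SubsampleResult(mean_count=float(np.mean(counts)), counts=counts)
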