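"""Cohort preprocessing: low-expression filtering, covariate/batch
residualization, hidden-factor removal, and per-disorder splitting.

Batch correction is done by including the source batch as a covariate in an
ordinary least-squares residualization, and hidden expression determinants
are estimated as the top singular vectors of the gene-centered matrix and
regressed out only when a one-way ANOVA finds them uncorrelated with
diagnosis.  Both are deliberately plain, fully specified stand-ins for
empirical-Bayes batch correction and latent-factor inference: the contract
(clean matrix, disease signal untouched) is the same, the machinery is
transparent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import validate_expression

__all__ = [
    "CohortBundle",
    "filter_low_expression",
    "regress_covariates",
    "remove_hidden_factors",
    "split_by_disorder",
]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "brain_region", "source_batch")


@dataclass
class CohortBundle:
    """An expression matrix (genes x samples) with its aligned phenotype
    table and an append-only provenance trail of applied transforms."""

    expression: pd.DataFrame
    samples: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        if list(self.expression.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample table are not aligned")

    def _derive(self, expression=None, samples=None, step=None) -> "CohortBundle":
        return CohortBundle(
            expression=self.expression if expression is None else expression,
            samples=self.samples if samples is None else samples,
            provenance=self.provenance + ([step] if step else []),
        )

    def controls(self) -> pd.DataFrame:
        return self.expression.loc[:, self.samples["diagnosis"] == "control"]

    def cases(self, disorder: str) -> pd.DataFrame:
        return self.expression.loc[:, self.samples["diagnosis"] == disorder]


def filter_low_expression(bundle: CohortBundle, threshold: float = 2.0) -> CohortBundle:
    """Drop genes whose across-sample median is strictly below ``threshold``."""
    if np.isnan(threshold) or threshold == np.inf:
        raise ValueError("threshold must not be +inf/NaN")
    med = bundle.expression.median(axis=1)
    keep = med >= threshold
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    out = bundle.expression.loc[keep]
    n_dropped = int((~keep).sum())
    log.info("filter_low_expression: dropped %d / %d genes (median < %g)",
             n_dropped, len(keep), threshold)
    return bundle._derive(
        expression=out,
        step={"transform": "filter_low_expression", "threshold": threshold,
              "n_dropped": n_dropped},
    )


def _encode_design(samples: pd.DataFrame, covariates) -> pd.DataFrame:
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise KeyError(f"covariate column(s) not in sample table: {missing}")
    parts = [pd.Series(1.0, index=samples.index, name="intercept")]
    for c in covariates:
        col = samples[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def regress_covariates(
    bundle: CohortBundle,
    covariates=DEFAULT_COVARIATES,
    on_collinear: str = "error",
) -> CohortBundle:
    """Per gene, OLS on intercept + encoded covariates; values are replaced
    by residuals plus the gene's grand mean.  Categorical covariates are
    dummy-encoded (first level dropped); include ``source_batch`` in the list
    to absorb batch offsets.  Idempotent.

    A rank-deficient design raises an error naming the collinear encoded
    columns; with ``on_collinear="drop"`` the redundant columns are dropped
    instead (the fitted subspace, hence the residuals, are unchanged —
    useful when e.g. one batch contains a single brain region)."""
    if on_collinear not in ("error", "drop"):
        raise ValueError("on_collinear must be 'error' or 'drop'")
    covariates = [c for c in covariates if c in bundle.samples.columns]
    design = _encode_design(bundle.samples, covariates)
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal does not reduce the rank
        redundant = [
            design.columns[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        if on_collinear == "error":
            raise ValueError(
                f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                f"collinear column(s): {redundant}"
            )
        keep, cur = [], 0
        for j in range(X.shape[1]):
            r_new = np.linalg.matrix_rank(X[:, keep + [j]])
            if r_new > cur:
                keep.append(j)
                cur = r_new
        log.info("regress_covariates: dropping %d collinear column(s): %s",
                 X.shape[1] - len(keep),
                 [c for i, c in enumerate(design.columns) if i not in keep])
        design = design.iloc[:, keep]
        X = design.to_numpy()
    Y = bundle.expression.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    grand_mean = Y.mean(axis=0)
    out = pd.DataFrame((resid + grand_mean).T,
                       index=bundle.expression.index,
                       columns=bundle.expression.columns)
    return bundle._derive(
        expression=out,
        step={"transform": "regress_covariates", "covariates": list(covariates)},
    )


def remove_hidden_factors(
    bundle: CohortBundle, k: int = 20, assoc_alpha: float = 0.05
) -> CohortBundle:
    """Estimate up to ``k`` hidden sample-level factors (top right-singular
    vectors of the gene-centered matrix) and regress out those uncorrelated
    with diagnosis.

    Each factor is tested by one-way ANOVA of its sample scores across
    diagnosis groups; factors with p >= ``assoc_alpha`` are projected out of
    every gene, factors with p < ``assoc_alpha`` are left in the data (they
    may carry disease signal).  Decisions are recorded in provenance."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n_samples = bundle.expression.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the sample count {n_samples}")
    if "diagnosis" not in bundle.samples.columns:
        raise KeyError("sample table lacks a 'diagnosis' column")

    Y = bundle.expression.to_numpy()
    gene_means = Y.mean(axis=1, keepdims=True)
    M = Y - gene_means
    # right-singular vectors = sample-level factors
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    k_eff = min(k, vt.shape[0])
    diag = bundle.samples["diagnosis"].to_numpy()
    groups = [np.flatnonzero(diag == d) for d in pd.unique(diag)]
    decisions = []
    remove_rows = []
    for i in range(k_eff):
        f = vt[i]
        if len(groups) < 2:
            p = 1.0
        else:
            p = float(stats.f_oneway(*[f[g] for g in groups]).pvalue)
        removed = p >= assoc_alpha
        if removed:
            remove_rows.append(i)
        decisions.append({"factor": i + 1, "anova_p": p, "removed": removed,
                          "singular_value": float(s[i])})
    if remove_rows:
        V = vt[remove_rows].T  # samples x r, orthonormal columns
        M = M - (M @ V) @ V.T
    out = pd.DataFrame(M + gene_means,
                       index=bundle.expression.index,
                       columns=bundle.expression.columns)
    log.info("remove_hidden_factors: removed %d of %d factors",
             len(remove_rows), k_eff)
    return bundle._derive(
        expression=out,
        step={"transform": "remove_hidden_factors", "k": k,
              "assoc_alpha": assoc_alpha, "decisions": decisions},
    )


def split_by_disorder(
    bundle: CohortBundle, disorders=("AUT", "SCZ", "BPD")
) -> dict:
    """One bundle per disorder: its cases plus the controls from the same
    source batch(es).  The gene universe is identical across outputs."""
    for col in ("diagnosis", "source_batch"):
        if col not in bundle.samples.columns:
            raise KeyError(f"sample table lacks a {col!r} column")
    diag = bundle.samples["diagnosis"]
    batch = bundle.samples["source_batch"]
    out = {}
    for d in disorders:
        is_case = diag == d
        if not is_case.any():
            raise ValueError(f"no cases for disorder {d!r}")
        case_batches = set(batch[is_case])
        for b in sorted(case_batches):
            if not ((diag == "control") & (batch == b)).any():
                raise ValueError(f"disorder {d!r}: no controls in batch {b!r}")
        keep = is_case | ((diag == "control") & batch.isin(case_batches))
        sub_samples = bundle.samples.loc[keep]
        sub_expr = bundle.expression.loc[:, sub_samples.index]
        out[d] = bundle._derive(
            expression=sub_expr, samples=sub_samples,
            step={"transform": "split_by_disorder", "disorder": d,
                  "n_cases": int(is_case.sum()),
                  "n_controls": int(keep.sum() - is_case.sum())},
        )
    return out
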