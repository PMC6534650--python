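import numpy as np
import pandas as pd
import pytest

from aberex import CohortBundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bundle(n_genes=50, n_cases=10, n_controls=20, seed=0, disorder="AUT",
                batch="I"):
    """A minimal single-disorder cohort of pure noise."""
    r = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    case_ids = [f"{disorder}{i:03d}" for i in range(n_cases)]
    ctl_ids = [f"CTL{i:03d}" for i in range(n_controls)]
    ids = case_ids + ctl_ids
    expr = pd.DataFrame(r.normal(5.0, 1.0, size=(n_genes, len(ids))),
                        index=genes, columns=ids)
    samples = pd.DataFrame({
        "diagnosis": [disorder] * n_cases + ["control"] * n_controls,
        "age": r.uniform(20, 70, len(ids)).round(1),
        "sex": r.choice(["F", "M"], len(ids)),
        "brain_region": r.choice(["BA19", "BA10"], len(ids)),
        "source_batch": [batch] * len(ids),
    }, index=pd.Index(ids, name="sample_id"))
    return CohortBundle(expr, samples)


@pytest.fixture
def noise_bundle():
    return make_bundle()


def planted_module_datasets(n_modules=3, module_size=30, n_noise=60,
                            n_samples=60, seed=0, loading=1.0, noise_sd=0.6,
                            n_datasets=3):
    """Datasets sharing block co-expression structure with independent
    per-dataset factors.  Returns (datasets, truth_labels, factors) where
    factors[d] is the (n_modules, n_samples) factor matrix of dataset d."""
    rng = np.random.default_rng(seed)
    n_genes = n_modules * module_size + n_noise
    truth = np.zeros(n_genes, dtype=int)
    datasets, factors = [], []
    for _ in range(n_datasets):
        X = rng.normal(0, 1, size=(n_genes, n_samples)) * noise_sd
        F = np.zeros((n_modules, n_samples))
        for m in range(n_modules):
            sl = slice(m * module_size, (m + 1) * module_size)
            truth[sl] = m + 1
            f = rng.normal(size=n_samples)
            F[m] = f
            lam = rng.uniform(0.7, 1.0, module_size) * loading
            X[sl] += np.outer(lam, f)
        datasets.append(X)
        factors.append(F)
    return datasets, truth, factors


def shared_control_bundles(seed=0, strength=2.0):
    """Three single-disorder bundles where SCZ and BPD share controls."""
    from aberex import CohortConfig, generate_cohort, split_by_disorder

    cfg = CohortConfig(
        n_genes=240, n_modules=3, module_size=30, sets_per_disorder=1,
        set_size=20, n_aut=18, n_scz=15, n_bpd=15, n_controls_batch1=20,
        n_controls_batch2=16, factor_sd=strength, n_hidden=0, batch_sd=0.0)
    expr, samples, truth = generate_cohort(cfg, seed=seed)
    return split_by_disorder(CohortBundle(expr, samples)), truth
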