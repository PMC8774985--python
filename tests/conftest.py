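import hypothesis
import numpy as np
import pandas as pd
import pytest

import acemod

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_cohort():
    """One synthetic cohort at the published size (1518 pairs), seed 1."""
    ds, manifest = acemod.generate_dataset(acemod.paper_like_config(seed=1))
    return ds, manifest


@pytest.fixture(scope="session")
def paper_arrays(paper_cohort):
    ds, _ = paper_cohort
    y1, y2, is_mz = ds.pair_arrays("y_inattention")
    m1, m2, _ = ds.pair_arrays("m_unhealthy")
    return y1, y2, m1, m2, is_mz


def make_twin_csv(path, rows):
    """Write a small per-individual CSV from a list of dicts."""
    cols = ["pair_id", "twin_order", "zygosity", "sex", "age",
            "inattention_raw", "hyperactivity_raw",
            "sugar_servings", "unhealthy_servings"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            raise AssertionError(f"test row missing {c}")
    df.to_csv(path, index=False)
    return path


def twin_row(pair_id, order, zyg="MZ", sex="female", age=30.0,
             ia=2, hi=3, sugar=1.5, unhealthy=3.0):
    return dict(pair_id=pair_id, twin_order=order, zygosity=zyg, sex=sex,
                age=age, inattention_raw=ia, hyperactivity_raw=hi,
                sugar_servings=sugar, unhealthy_servings=unhealthy)


def oracle_pair_deviance(y, mean, cov):
    """Brute-force -2 log bivariate-normal density for one pair.

    Independent of the package's vectorized likelihood: scipy's
    multivariate_normal does the density arithmetic.
    """
    from scipy.stats import multivariate_normal
    return -2.0 * float(multivariate_normal(mean=mean, cov=cov).logpdf(y))


def oracle_moderated_deviance(params, y1, y2, m1, m2, is_mz):
    """Per-pair oracle deviance of the moderation model.

    The per-pair means and covariances are rebuilt here from the model
    definition (moderated paths), not taken from the package.
    """
    total = 0.0
    for i in range(len(y1)):
        r = 1.0 if is_mz[i] else 0.5
        pa1 = params.a + params.beta_a * m1[i]
        pa2 = params.a + params.beta_a * m2[i]
        pc1 = params.c + params.beta_c * m1[i]
        pc2 = params.c + params.beta_c * m2[i]
        pe1 = params.e + params.beta_e * m1[i]
        pe2 = params.e + params.beta_e * m2[i]
        cov = np.array([
            [pa1**2 + pc1**2 + pe1**2, r*pa1*pa2 + pc1*pc2],
            [r*pa1*pa2 + pc1*pc2, pa2**2 + pc2**2 + pe2**2],
        ])
        mean = [params.m + params.beta_m * m1[i],
                params.m + params.beta_m * m2[i]]
        total += oracle_pair_deviance([y1[i], y2[i]], mean, cov)
    return total
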