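import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acecontact import coevolution, core, msa, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_msa(rows, labels=None, query_index=0):
    if labels is None:
        labels = [f"s{k}" for k in range(len(rows))]
    return msa.Msa.from_rows(rows, labels, query_index)


@pytest.fixture(scope="session")
def default_family():
    """The default synthetic family (seed 7) with its planted ground truth."""
    spec = synthetic.default_spec(7)
    aln, truth = synthetic.generate_family(spec)
    return spec, aln, truth


@pytest.fixture(scope="session")
def default_ace_result(default_family):
    """Full enhancement run on the default family against the planted map."""
    spec, aln, truth = default_family
    nested = msa.make_nested_msas(aln)
    reference = set(truth.dominant_pairs) | set(truth.alternative_pairs)
    result = core.run_ace(nested, [coevolution.score_mi_apc], reference)
    return spec, truth, result


def random_msa(rng, depth=12, n_cols=20, gap_frac=0.1):
    """A random alignment whose first row (the query) is gap-free."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    codes = rng.integers(0, 20, size=(depth, n_cols))
    gaps = rng.random((depth, n_cols)) < gap_frac
    gaps[0] = False
    codes[gaps] = 20
    return make_msa(["".join(r) for r in aa[codes]])
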