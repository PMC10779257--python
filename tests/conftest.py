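import pytest

from genefamkit.family_identification import IdentificationConfig, run_funnel
from genefamkit.phylogeny import nj_tree, pairwise_poisson_distance
from genefamkit.synthetic_data import SimulationConfig, simulate_family

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    """One synthetic study bundle shared by the whole suite."""
    return simulate_family(SimulationConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def ref_records(bundle):
    return [bundle.refs[r] for r in sorted(bundle.refs)]


@pytest.fixture(scope="session")
def ident_config(ref_records):
    return IdentificationConfig(reference_ids=tuple(r.id for r in ref_records))


@pytest.fixture(scope="session")
def funnel_result(bundle, ref_records, ident_config):
    """Full identification funnel on the bundle, including the clade stage."""
    proteins = list(bundle.proteins.values())
    pre = run_funnel(bundle.hits, bundle.domain_hits, proteins, None,
                     ident_config)
    cand = [bundle.proteins[c] for c in sorted(pre.domain_filtered)] + ref_records
    tree = nj_tree(pairwise_poisson_distance(cand))
    return run_funnel(bundle.hits, bundle.domain_hits, proteins, tree,
                      ident_config)
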