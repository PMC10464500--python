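import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_genome():
    """A deterministic 100-kb single-contig genome."""
    rng = np.random.default_rng(12345)
    bases = np.array(list("ACGT"))
    return {"chr1": "".join(bases[rng.integers(0, 4, size=100_000)])}


@pytest.fixture(scope="session")
def two_signature_cohort():
    """50 samples x 5,000 mutations from two disjoint-support truth signatures.

    One signature is alkylation-like (T>C / T>A peaks), the other a C-centric
    clock; exposures are Dirichlet-sampled.  Shared across the extraction,
    model-selection and acceptance tests because simulation plus NMF is the
    slowest fixture.
    """
    from ucsomatic import catalogs, synthetic as syn
    from ucsomatic.signatures import SignatureMatrix

    rng = np.random.default_rng(7)
    sigs = SignatureMatrix(
        data=pd.DataFrame(
            {"PT": syn.pt_like_signature(), "CLOCK": syn.clock_like_signature()}
        ),
        scheme="SBS96",
    )
    n = 50
    samples = [f"S{i + 1:02d}" for i in range(n)]
    exposures = pd.DataFrame(
        rng.dirichlet([1.5, 1.5], size=n), index=samples, columns=sigs.names
    )
    config = syn.SimulationConfig(
        seed=7,
        n_samples=n,
        mutations_per_sample=5_000,
        signatures=sigs,
        exposures=exposures,
    )
    genome, exome, transcripts = syn.generate_reference(config)
    variants, truth = syn.simulate_variants(config, genome, exome)
    catalog = catalogs.build_catalog(variants, genome, "SBS96")
    opps = catalogs.compute_opportunities(genome, exome, flank=0)
    return {
        "config": config,
        "genome": genome,
        "exome": exome,
        "variants": variants,
        "truth": truth,
        "catalog": catalog,
        "opportunities": opps,
    }


def territory_signatures(signatures, opportunities):
    """Truth signatures reweighted into the simulated territory's context space."""
    from ucsomatic.catalogs import SBS96_CHANNELS, channel_context

    w = np.array(
        [opportunities.counts[channel_context(c)] for c in SBS96_CHANNELS]
    )
    out = {}
    for name in signatures.names:
        t = signatures.column(name) * w
        out[name] = t / t.sum()
    return out
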