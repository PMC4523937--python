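import logging

import pytest

from fdmrank import (
    FixtureConfig,
    aggregate_ranks,
    compute_individual_ranks,
    generate_fixture,
)

logging.getLogger("fdmrank").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic fixture (seed 0)."""
    return generate_fixture(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def ranking(bundle):
    """Four individual rank vectors over the default fixture."""
    return compute_individual_ranks(
        bundle.dmrs,
        bundle.genes,
        bundle.expression,
        bundle.conservation,
        bundle.tfbs,
        bundle.dhs,
        bundle.enhancers,
        bundle.insulators,
        bundle.methylation,
    )


@pytest.fixture(scope="session")
def full_aggregation(ranking):
    return aggregate_ranks(
        [ranking.ranks[f] for f in ("expression", "conservation",
                                    "genomic_features", "dynamics")],
        label="full",
    )
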