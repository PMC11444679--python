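import pytest

from pyomine import simulate as sim
from pyomine import substrates as subs
from pyomine.seqcore import ProteinSequence


@pytest.fixture(scope="session")
def fixture_spec():
    return sim.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixtures(fixture_spec):
    """The default 5-genome synthetic dataset (seed 1, zero instance noise)."""
    return sim.generate_fixtures(fixture_spec)


@pytest.fixture(scope="session")
def refset(fixtures):
    return subs.ReferenceSet(
        [
            subs.ReferenceADomain(
                r["id"],
                r["substrate"],
                ProteinSequence(r["id"], r["amotif45_sequence"]),
                r["source"],
            )
            for r in fixtures.adomain_refs
        ]
    )


@pytest.fixture(scope="session")
def pipeline_result(fixtures, refset):
    from pyomine import pipeline as pipe
    from pyomine.config import PipelineConfig

    rrefs = [ProteinSequence(r["id"], r["sequence"]) for r in fixtures.receptor_refs]
    rclasses = {r["id"]: r["class"] for r in fixtures.receptor_refs}
    return pipe.run_pipeline(
        PipelineConfig(),
        fixtures.genomes,
        refset,
        rrefs,
        rclasses,
        fixtures.domain_seeds,
        clades=fixtures.clades,
    )


def truth_receptor_by_start(fixtures, strain_id):
    """Planted receptors of a strain keyed by CDS start coordinate."""
    return {
        r["start"]: r
        for r in fixtures.ground_truth["strains"][strain_id]["receptors"]
    }
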