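import numpy as np
import pytest

from tandemtrace.align import ScoringParams
from tandemtrace.loci import call_loci, segment_locus
from tandemtrace.simulate import build_tandem_locus, render


@pytest.fixture(scope="session")
def default_params() -> ScoringParams:
    return ScoringParams()

@pytest.fixture(scope="session")
def global_params() -> ScoringParams:
    return ScoringParams(free_end_gaps=False)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fresh_tandem_locus():
    """Three tandem genes, zero drift: segments plus the rendered genome."""
    state = build_tandem_locus(seed=11, n_genes=3, igr_drift=0.0)
    genome, genes, domains = render(state)
    loci_ = call_loci(
        genes, {g.id for g in genes},
        contig_lengths={c: len(s) for c, s in genome.items()},
    )
    segments = segment_locus(loci_[0], genome)
    return {
        "state": state,
        "genome": genome,
        "genes": genes,
        "domains": domains,
        "loci": loci_,
        "segments": segments,
    }
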