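import numpy as np
import pytest

from ppfm.adh import make_default_anchors, make_reference
from ppfm.io import SequenceRecord
from ppfm.screen import ClusterGene, ReferenceCluster
from ppfm.synth import GenomeSpec, forge_genome, random_protein


@pytest.fixture(scope="session")
def reference():
    return make_reference()


@pytest.fixture(scope="session")
def anchors(reference):
    return make_default_anchors(reference)


@pytest.fixture(scope="session")
def mxa_cluster():
    """A 14-gene reference cluster with synthetic member proteins."""
    genes = []
    for i in range(14):
        rng = np.random.default_rng(700 + i)
        name = f"mxa{chr(ord('A') + i)}"
        genes.append(
            ClusterGene(
                name=name,
                protein=SequenceRecord(
                    id=name, seq=random_protein(rng, 260), alphabet="aa"
                ),
                essential=i < 3,
            )
        )
    return ReferenceCluster(name="mxa", genes=tuple(genes))


@pytest.fixture(scope="session")
def small_genome():
    spec = GenomeSpec(
        n_replicons=1,
        replicon_lengths=(30_000,),
        n_genes=25,
        gc_target=66.0,
        seed=42,
    )
    return forge_genome(spec, "small")


def make_genome(length=30_000, n_genes=25, gc=66.0, seed=0, genome_id="g"):
    return forge_genome(
        GenomeSpec(
            n_replicons=1,
            replicon_lengths=(length,),
            n_genes=n_genes,
            gc_target=gc,
            seed=seed,
        ),
        genome_id,
    )
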