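import pytest

from ilpminer.records import SequenceRecord
from ilpminer.simulate import (
    gene_model_spec,
    make_genome,
    make_ilp_gene,
    reference_panel,
)


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def family_genes():
    """One gene build per family, fixed seed."""
    return {
        fam: make_ilp_gene(gene_model_spec(fam), seed=11, gene_id=f"{fam}_g")
        for fam in ("insulin", "aIGF", "gonadulin", "relaxin")
    }


@pytest.fixture(scope="session")
def small_genome():
    """One triplication cluster in 60 kb of decoy."""
    return make_genome(
        n_clusters=1,
        cluster_composition=("gonadulin", "aIGF", "relaxin"),
        intergenic_distances=(5000, 8000),
        decoy_length=60_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def family_panel_seqs():
    """Three members per family, for similarity-tree grouping checks."""
    seqs = []
    for fam in ("insulin", "aIGF", "gonadulin", "relaxin"):
        for k in (1, 2, 3):
            g = make_ilp_gene(gene_model_spec(fam), seed=100 + k, gene_id=f"{fam}{k}")
            seqs.append(
                SequenceRecord(f"{fam}{k}", g.proteins[f"{fam}{k}.t1"], "protein")
            )
    return seqs
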