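import hypothesis
import pandas as pd
import pytest

from clonearch import (
    AlleleCountRecord,
    FilterConfig,
    SimulationConfig,
    build_genotype_matrix,
    simulate_clone_tree,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def filter_config():
    return FilterConfig()


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def chain_tree():
    """Three-mutation linear chain: WT -> {m01} -> {m01,m02} -> {m01,m02,m03}."""
    return simulate_clone_tree(SimulationConfig(n_mutations=3, branching_prob=0.0, seed=0))


def make_record(**kw):
    """Well-formed tumour record that passes every filter by default."""
    base = dict(
        sample_id="CD34_TP1",
        source_class="primary_CD34",
        mutation_id="m01",
        gene="SF3B1",
        chrom="2",
        pos=198_266_834,
        ref="A",
        alt="G",
        alt_reads=368,
        total_reads=800,
        fwd_alt_reads=184,
        rev_alt_reads=184,
        mean_align_score=60.0,
        mean_base_quality=35.0,
        flank_left="ACCAAC",
        flank_right="TGACTG",
    )
    base.update(kw)
    return AlleleCountRecord(**base)


def make_normal(**kw):
    base = dict(
        sample_id="skin",
        source_class="normal_skin",
        mutation_id="m01",
        chrom="2",
        pos=198_266_834,
        alt_reads=0,
        total_reads=800,
    )
    base.update(kw)
    return AlleleCountRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def normal_factory():
    return make_normal


def matrix_from_signatures(signatures, mutations, depth=200):
    """Colony matrix whose rows realise the given mutation-set signatures."""
    rows = []
    for i, sig in enumerate(signatures):
        cid = f"colony{i + 1:03d}"
        for m in mutations:
            alt = int(depth * 0.5) if m in sig else 0
            rows.append({"colony_id": cid, "mutation_id": m,
                         "alt_reads": alt, "total_reads": depth})
    return build_genotype_matrix(pd.DataFrame(rows), panel=list(mutations))


@pytest.fixture
def signature_matrix():
    return matrix_from_signatures
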