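import random

import pytest

from tehits import Hit, Strand, generate_fixture


def make_hit(location="chr1", start=100, end=200, strand=Strand.PLUS,
             label="TE1", hit_id=None, **kw):
    """Construct a Hit with sensible defaults for unit tests."""
    if hit_id is None:
        hit_id = f"{label}_{location}_{start}_{end}_{random.random()}"
    return Hit(hit_id=hit_id, location=location, seq_start=start,
               seq_end=end, strand=strand, group_label=label, **kw)


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Divergence-0 fixture: 20 planted copies, mixed strands."""
    outdir = tmp_path_factory.mktemp("fx_clean")
    return generate_fixture(outdir, n_sequences=3, seq_length=10_000,
                            n_insertions=20, divergence=0.0, seed=11)


@pytest.fixture(scope="session")
def diverged_fixture(tmp_path_factory):
    """5%-diverged fixture exercising mismatch bookkeeping and filters."""
    outdir = tmp_path_factory.mktemp("fx_div")
    return generate_fixture(outdir, n_sequences=3, seq_length=10_000,
                            n_insertions=20, divergence=0.05, seed=23)


@pytest.fixture(scope="session")
def fragmented_fixture(tmp_path_factory):
    """Fixture whose hit files report each planted copy as up to three
    fragments separated by gaps of at most 80 bases."""
    outdir = tmp_path_factory.mktemp("fx_frag")
    return generate_fixture(outdir, n_sequences=3, seq_length=10_000,
                            n_insertions=12, divergence=0.0, seed=37,
                            fragments_per_hit=3, fragment_max_gap=80)
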