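import pytest

from oncopanel import (
    build_reference_standard,
    make_snv_panel,
    simulate_pileups,
)


@pytest.fixture(scope="session")
def small_panel():
    return make_snv_panel(12, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    """Six SNVs spanning all three MAF strata on the small panel."""
    mafs = [0.02, 0.04, 0.06, 0.08, 0.20, 0.50]
    spec = []
    for target, maf in zip(small_panel[:6], mafs):
        alt = next(b for b in "ACGT" if b != target.ref_base)
        spec.append(((target.chrom, target.pos, target.ref_base, alt), maf))
    return build_reference_standard(spec, "mini-standard", panel=small_panel)


@pytest.fixture(scope="session")
def deep_pileups(small_panel, small_truth):
    return simulate_pileups(
        small_truth, small_panel, median_depth=1000, error_rate=0.001, seed=5
    )


@pytest.fixture(scope="session")
def panel_contexts(small_panel):
    return {
        (t.chrom, t.pos): (t.ref_context, t.context_offset) for t in small_panel
    }
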