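import pytest

import gemreduce as gr


@pytest.fixture(scope="session")
def default_toy():
    """Plain 3-subsystem toy: one aminated building block, one 2-step bridge."""
    return gr.make_toy_gem(gr.ToyGemSpec(seed=0))


@pytest.fixture(scope="session")
def default_d0(default_toy):
    return gr.build_d0(
        default_toy.model, default_toy.subsystem_defs, default_toy.exclusions
    )


@pytest.fixture(scope="session")
def rich_toy():
    """Toy with every optional structure: alternative routes, a
    medium-supplied building block, an alternative carbon source, and an
    extracellular substrate with a unique catabolic route."""
    return gr.make_toy_gem(
        gr.ToyGemSpec(
            seed=7,
            substrate_route=True,
            bbb_in_medium=True,
            alt_carbon=True,
            planted_bbb_routes=(
                gr.Route("bbb0", kinds=("aminate", "phos"), n_alternatives=2),
            ),
        )
    )


@pytest.fixture(scope="session")
def rich_d0(rich_toy):
    return gr.build_d0(rich_toy.model, rich_toy.subsystem_defs, rich_toy.exclusions)
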