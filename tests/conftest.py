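import pytest

from oncoprofile.genome import toy_genome


@pytest.fixture(scope="session")
def spec():
    return toy_genome()


@pytest.fixture(scope="session")
def expression_cohort():
    """The reference 5-class synthetic cohort used across TOO tests."""
    from oncoprofile.simulate import gen_expression_cohort

    cohort, truth = gen_expression_cohort(
        n_classes=5, n_per_class=50, n_genes=200, n_informative=40,
        effect_log2fc=4.0, seed=1,
    )
    cohort.normalize()
    return cohort, truth
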