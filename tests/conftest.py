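import logging

import pytest

# keep dropped-focus / skipped-comparison warnings out of test output
logging.getLogger("quadfoci").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fibroblast_results():
    """Per-image quantification of the full fibroblast preset cohort.

    Session-scoped: the cohort is the most expensive fixture and several
    tests share it.
    """
    from quadfoci.pipeline import quantify_cohort
    from quadfoci.simulate import generate_cohort

    return quantify_cohort(generate_cohort("fibroblast", 1234))


@pytest.fixture()
def small_spec():
    from quadfoci.simulate import SimImageSpec

    return SimImageSpec(shape=(256, 256), n_cells=5)
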