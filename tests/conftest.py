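import pytest

from pmrisk import la_lbma_case, run_pipeline


@pytest.fixture(scope="session")
def case():
    """The packaged LA-LBMA case study."""
    return la_lbma_case()


@pytest.fixture(scope="session")
def report(case):
    """Full pipeline report on the LA-LBMA case."""
    return run_pipeline(case)


@pytest.fixture(scope="session")
def scorecards(case):
    from pmrisk.mcda import ScoreCard

    return [
        ScoreCard.from_raw(alt, case.assessments[alt], case.criteria)
        for alt in case.assessments
    ]
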