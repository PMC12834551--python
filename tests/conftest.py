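import pytest

from healthindex import (
    Dass21Responses,
    InstrumentResponses,
    IpaqResponses,
    RespondentProfile,
    SfffqResponses,
    default_config,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture()
def healthy_profile():
    """A 45-year-old with every measurable factor in its low-risk band."""
    return RespondentProfile(
        age=45,
        sex="male",
        height=175.0,
        weight=70.0,
        waist=85.0,
        sbp=110.0,
        dbp=70.0,
        ldl=2.0,
        fbg=4.8,
        hba1c=5.0,
    )


@pytest.fixture()
def healthy_responses():
    """Questionnaire answers that put every instrument domain at low risk."""
    return InstrumentResponses(
        dass21=Dass21Responses(items=(0,) * 21),
        ipaq_sf=IpaqResponses(vigorous_days=5, vigorous_min_per_day=60.0),
        sfffq=SfffqResponses(fruit=5, vegetables=5, oily_fish=3, non_milk_sugar=0, fat=0),
    )
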