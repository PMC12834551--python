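"""Score a single respondent and print the composite, category and advice.

A 52-year-old former smoker with borderline blood pressure and moderate
physical activity: three factors band moderate, pulling the composite to 80
— just below the healthy cutoff of 82, so she lands in the at-risk category
with three targeted advice cards.
"""

from healthindex import (
    Dass21Responses,
    InstrumentResponses,
    IpaqResponses,
    RespondentProfile,
    SfffqResponses,
    assess,
)

profile = RespondentProfile(
    age=52,
    sex="female",
    height=162.0,
    weight=60.0,  # BMI 22.9 -> low risk
    waist=75.0,
    smoking="former",  # moderate risk
    sbp=128.0,
    dbp=78.0,  # moderate risk (SBP 120-139)
    ldl=2.2,
    fbg=5.1,
    hba1c=5.3,
)

responses = InstrumentResponses(
    dass21=Dass21Responses(items=(0,) * 21),  # no distress -> low risk
    ipaq_sf=IpaqResponses(walking_days=5, walking_min_per_day=40.0),  # moderate activity
    sfffq=SfffqResponses(fruit=4, vegetables=4, oily_fish=1, non_milk_sugar=2, fat=2),
)

result = assess(profile, responses)

print(f"composite (raw):     {result.composite:.2f}")
print(f"composite (display): {result.composite_rounded}")
print(f"category:            {result.category.value}")
for domain, score in result.domain_scores.items():
    print(f"  {domain:<18} raw={score.raw:6.2f}  band={score.band.value}")
print(f"advice cards:        {len(result.advice)}")
for card in result.advice:
    print(f"  [{card.message_key}] {card.message_text[:64]}...")

# The composite is the weighted mean of the four domain scores (frailty is
# not assessed under 60, its weight redistributes to 0.25 each); the category
# comes from the rounded composite (>=82 healthy, 31-81 at risk, <=30 poor).
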