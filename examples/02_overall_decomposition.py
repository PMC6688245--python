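"""Split the urban-rural delivery gap under the four weighting schemes.

Each scheme prices endowment differences with a different coefficient
vector: the urban coefficients (omega=1), the rural ones (omega=0), their
average (0.5) or the sample-share blend.  All schemes agree on the total;
they differ in how the residual splits into discrimination against the
rural group versus favoritism of the urban group.
"""

from obdecomp import decompose_table, default_ghana_spec, generate_survey, window_exclusions
from obdecomp.design import OUTCOME_TERMS

table = generate_survey(default_ghana_spec(), n=13_802, seed=1)
excl = window_exclusions(table, list(OUTCOME_TERMS))

for scheme in ("oaxaca", "blinder", "reimers", "cotton"):
    res, fits, _ = decompose_table(table, scheme, exclude_terms=excl)
    comps = ", ".join(
        f"{k}={v:+.3f} ({res.percent_of_total[k]:.1f}%)" for k, v in res.components().items()
    )
    print(f"{scheme:8s} omega={res.omega:.2f}  total={res.total:.3f}  {comps}")
# The explained (endowment) component dominates under every weighting:
# most of the gap comes from rural women's poorer endowments (wealth,
# education, antenatal care), not from differing coefficients.
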