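"""Why a fixed-total binomial model fails for paired counts.

Eight periods of success/failure counts that double together: because the
total number of trials is random, the two outcome series are perfectly
positively correlated even though the success probability never moves from
one half. A model that fixes the total would force a negative association.
"""

import pandas as pd

import poispair as pp

counts = [10, 20, 30, 40, 50, 60, 70, 80]
df = pd.DataFrame(
    {"subject": ["s"] * 8, "time": range(1, 9), "y1": counts, "y2": counts}
)
panel = pp.panel_from_dataframe(df)

corr = pp.success_failure_correlation(panel)[0]
prop = pp.success_proportion(panel)
print(f"correlation between success and failure series: {corr}")
print(f"overall success proportion:                     {prop}")
print()
print(
    "The counts rise together (correlation 1) while successes stay exactly\n"
    "half of the trials: association between the series carries information\n"
    "about shared instability, not about the success probability."
)
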