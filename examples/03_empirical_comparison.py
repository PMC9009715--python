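"""Empirical walking-economy equations over the validation trial grid.

Evaluates the Pandolf and Looney equations for four validation subjects
walking at 1.3 and 0.8 m/s and prints the per-condition means.  With no
carried load the Pandolf cost is mass-independent, so the spread across
subjects at one speed is zero and the SD reflects only the two speeds.
"""

import numpy as np

from jointmee import SubjectProfile, WalkingCondition, looney_cost, pandolf_cost
from jointmee.empirical import model_comparison_table

subjects = [
    SubjectProfile("S04", mass=90.58, height=1.72, age=34, sex="male"),
    SubjectProfile("S08", mass=59.25, height=1.70, age=25, sex="male"),
    SubjectProfile("S09", mass=68.72, height=1.70, age=20, sex="female"),
    SubjectProfile("S12", mass=67.28, height=1.69, age=21, sex="female"),
]
speeds = [1.3] * 4 + [0.8] * 4

level = [(s, WalkingCondition(v)) for s, v in zip(subjects * 2, speeds)]
uphill = [(s, WalkingCondition(v, grade=8.0)) for s, v in zip(subjects * 2, speeds)]

pandolf_level = [pandolf_cost(s.mass, c) for s, c in level]
pandolf_uphill = [pandolf_cost(s.mass, c) for s, c in uphill]
looney_level = [looney_cost(c) for _, c in level]

print(f"Pandolf level mean:  {np.mean(pandolf_level):.2f} J/kg/m")
print(f"Pandolf uphill mean: {np.mean(pandolf_uphill):.2f} J/kg/m")
print(f"Looney level mean:   {np.mean(looney_level):.2f} J/kg/m")

# same numbers in tidy-table form, against a nominal measured cost
table = model_comparison_table(
    {
        "pandolf": lambda s, c: pandolf_cost(s.mass, c),
        "looney": lambda s, c: looney_cost(c),
    },
    level,
    [4.6] * 8,
)
print()
print(table.to_string(index=False))
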