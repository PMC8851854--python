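"""MW-scores and taxon contribution percentages on a two-genome community.

Genome g1 (coverage 10) encodes function f1; genome g2 (coverage 30)
encodes f1 and f2.  The MW-score of each function is its coverage-weighted
share of the community's functional capacity; contribution percentages
split each function's share across taxon groups.
"""

import pandas as pd

from cycleprofiler import CommunityProfile, contribution_percentages, mw_scores

profile = CommunityProfile(
    presence=pd.DataFrame([[1, 0], [1, 1]], index=["g1", "g2"], columns=["f1", "f2"]),
    coverage=pd.Series({"g1": 10.0, "g2": 30.0}),
    groups=pd.Series({"g1": "Nitrospirota", "g2": "Gammaproteobacteria"}),
)

mw = mw_scores(profile)
cperc = contribution_percentages(profile)
print("MW-scores (sum to 1):")
print(mw.to_string(float_format=lambda v: f"{v:.4f}"))
print("\nContribution percentages (each function sums to 100%):")
print(cperc.to_string(float_format=lambda v: f"{v:.1f}"))
print()
print("f1 is carried by both genomes (weight 10+30 of 70 total -> 0.5714);")
print("f2 only by g2 (30/70 -> 0.4286).  g2's coverage gives its group 75%")
print("of f1 and all of f2.")
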