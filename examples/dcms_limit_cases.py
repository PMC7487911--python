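"""The composite's two printed limit cases, worked by hand-sized inputs.

Three statistics each give p = 0.1 at one SNP. If the statistics are
mutually uncorrelated the weight factor is 1 per statistic and the composite
is the sum of the three logit terms, 3*ln(9) ~ 6.5917; if they are perfectly
correlated the weight factor is 1/3 and the composite is their average,
ln(9) ~ 2.1972 — correlated statistics are prevented from triple-counting
the same evidence.
"""

import numpy as np

from dcmscan.composite import CorrMatrix, PMatrix, dcms_scores

names = ["stat1", "stat2", "stat3"]
P = PMatrix(np.array([[0.1, 0.1, 0.1]]), names)

identity = CorrMatrix(np.eye(3), names)
ones = CorrMatrix(np.ones((3, 3)), names)

print("weight factors, uncorrelated :", np.round(1 / identity.weights(), 4))
print("weight factors, correlated   :", np.round(1 / ones.weights(), 4))
print("DCMS, uncorrelated (sum)     : %.4f" % dcms_scores(P, identity)[0])
print("DCMS, correlated (average)   : %.4f" % dcms_scores(P, ones)[0])
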