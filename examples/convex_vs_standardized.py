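"""Why convex weights, not rescaled standardized weights.

Two intelligence tests on a 0-100 scale: Test 1 barely separates the
children ({49,50,51}), Test 2 separates them well ({0,50,100}).  The
standardized fit gives both tests the same weight, and its ad-hoc
unstandardized rescaling then makes the *less* informative test 50 times
more influential.
"""

import pandas as pd

from convexgsca import ModelSpec, fit_cvx, fit_std, moments_from_data, validate_spec
from convexgsca.als_estimation import rescale_weights_unstandardized

data = pd.DataFrame({"t1": [49.0, 50.0, 51.0], "t2": [0.0, 50.0, 100.0]})
spec = validate_spec(ModelSpec({"intelligence": ["t1", "t2"]}))
moments = moments_from_data(data)

sfit = fit_std(spec, moments, compute_indexes=False)
W_uni, means = rescale_weights_unstandardized(sfit, moments)
print("standardized weights:     ", sfit.params.W[:, 0].round(3))
print("ad-hoc rescaled weights:  ", W_uni[:, 0].round(3), " (t1 is 50x t2!)")

# the 3-row toy is perfectly collinear, so for the convex fit give the two
# tests some independent variation (convex weights need a full-rank block)
data2 = pd.DataFrame({
    "t1": [49.0, 50.0, 51.0, 49.5, 50.5, 50.0],
    "t2": [0.0, 50.0, 100.0, 60.0, 40.0, 52.0],
})
cfit = fit_cvx(spec, moments_from_data(data2), compute_indexes=False)
print("convex weights:           ", cfit.params.W[:, 0].round(3))
print("convex component mean/SD: ",
      round(cfit.component_means[0], 3), "/", round(cfit.component_sds[0], 3))
print("\nThe convex weights are contribution rates (non-negative, sum to 1)")
print("and the component keeps the 0-100 scale: its SD of ~16 comes from the")
print("test that actually spreads the children out, instead of being pinned")
print("at 1 the way the rescaled standardized component's is.")
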