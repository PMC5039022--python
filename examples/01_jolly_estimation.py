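"""Estimate a population total from one aerial strip-transect survey.

Builds a tiny survey sample by hand (4 sampled units of 5 km^2 in a
100 km^2 zone of 20 units) and applies the Jolly Method 2 ratio estimator.
"""

from rangetrends.jolly import SurveySample, jolly_method2

sample = SurveySample(
    zone_area=100.0,        # Z: census zone, km^2
    total_units=20,         # N: sampling units in the zone
    unit_areas=[5, 5, 5, 5],  # z_i: area of each sampled unit
    counts=[2, 4, 6, 8],      # y_i: animals counted in each unit
    county="demo", species="zebra",
)
est = jolly_method2(sample)

print(f"density R_hat : {est.density:.3f} animals/km^2")
print(f"total   Y_hat : {est.estimate:.1f} animals")
print(f"SE(Y_hat)     : {est.se:.3f} animals")
# The density 20/20 = 1 animal/km^2 scales to 100 animals in the zone; the
# SE of ~23 reflects the between-unit count spread after the
# finite-population correction N(N-n)/n.
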