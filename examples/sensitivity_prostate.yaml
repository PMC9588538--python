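# Example confounding-function specification for a three-arm comparative
# effectiveness analysis (1 = surgery, 2 = radiotherapy + hormone therapy,
# 3 = radiotherapy + brachytherapy).
#
# Signs encode the belief that clinicians steer healthier patients toward
# arm 1: subjects observed under arm 1 would outlive, under either treatment,
# subjects observed under the radiotherapy arms.  Bounds are omega = 0.75
# units of the residual SD unexplained by measured covariates.  Between the
# two radiotherapy arms the direction is uncertain; run the analysis once per
# plausible sign combination for c_2_3 / c_3_2 ("+"/"-", "-"/"+", "+"/"+",
# "-"/"-") and compare.
c_1_2: {sign: "+", omega: 0.75}
c_2_1: {sign: "-", omega: 0.75}
c_1_3: {sign: "+", omega: 0.75}
c_3_1: {sign: "-", omega: 0.75}
c_2_3: {sign: "+", omega: 0.75}
c_3_2: {sign: "-", omega: 0.75}
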