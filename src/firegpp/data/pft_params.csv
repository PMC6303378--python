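# Plant functional type parameters.
# vcmax25 [umol m-2 s-1], jmax_ratio = Jmax25/Vcmax25, Ball-Berry slope m [-],
# intercept b [mol m-2 s-1], ozone damage sensitivities a_low/a_high
# [(nmol m-2 s-1)^-1] bracketing species tolerance, flux threshold t_o3
# [nmol m-2 s-1].  Damage coefficients are calibration artifacts produced by
# firegpp.calibrate (deciduous broadleaf percent-GPP-per-ppbv response matched
# to the observed envelope); thresholds are 1.6 for woody and 5.0 for
# herbaceous PFTs.
pft_name,pathway,vcmax25,jmax_ratio,ball_berry_slope,ball_berry_intercept,a_low,a_high,t_o3
evergreen_needleleaf_forest,C3,45.0,1.67,9.0,0.01,0.015575,0.058707,1.6
deciduous_broadleaf_forest,C3,55.0,1.67,9.0,0.01,0.031150,0.117413,1.6
evergreen_broadleaf_forest,C3,50.0,1.67,9.0,0.01,0.031150,0.117413,1.6
shrubland,C3,40.0,1.67,9.0,0.01,0.023962,0.086263,1.6
tundra,C3,35.0,1.67,9.0,0.01,0.015575,0.058707,1.6
c3_grass,C3,50.0,1.67,9.0,0.01,0.047924,0.172526,5.0
c4_grass,C4,30.0,1.67,4.0,0.04,0.031150,0.117413,5.0
c3_crop,C3,70.0,1.67,9.0,0.01,0.062301,0.234827,5.0
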