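# Printed endpoint summaries of the three-step curtain experiments used to
# calibrate the shipped default parameters.
# Units: percent for all observables. norm_length / norm_intensity are the
# 30->40-min normalized increments (L_t - L_30min)/L_30min etc.; free_fraction
# is the unoccupied lattice percentage (reported for the reference simulation,
# quoted to ~+-5).
# Rows with a ref_condition are paired differences (condition - ref_condition)
# of the 40-min normalized length increment at the same fold: the source
# reports the 15 mM vs 150 mM differences, not 15 mM absolutes.
# weight multiplies the 1/sem^2 residual weight.  The fold-25 intensity
# endpoint carries weight 0: with intensity = bound-molecule count and
# footprints of 20-30 nt, the count ratio N(40min)/N(30min) is bounded by
# (0.63*L/20)/(0.20*L/30) ~ 4.7 given the reported free fractions, so a
# +648% increment is outside the model class (a structural outlier that
# otherwise dominates the least squares and biases every feasible record);
# it is retained here for reporting and tested as a known model limitation.
condition,ref_condition,fold,time_s,observable,value,sem,weight
150mM,,25,2400,norm_length,36.5,10.1,1
150mM,,25,2400,norm_intensity,648.3,60.1,0
150mM,,25,1800,free_fraction,80.0,2.5,1
150mM,,25,2400,free_fraction,37.0,2.5,1
150mM,,0,2400,norm_intensity,-0.1,5.9,1
15mM,,0,2400,norm_intensity,-4.8,9.2,1
15mM,150mM,1,2400,norm_length,3.2,2.5,1
15mM,150mM,4,2400,norm_length,11.8,1.0,1
15mM,150mM,10,2400,norm_length,17.1,3.3,1
15mM,150mM,25,2400,norm_length,19.1,4.2,1
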