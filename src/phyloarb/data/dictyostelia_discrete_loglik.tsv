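# Published root marginal log-likelihoods from binary-trait ancestral state
# reconstruction of 13 Dictyostelia traits over the rival AAPPRS (6-protein)
# and SSU rDNA phylogenies of the same 55 taxa. The higher (less negative)
# log-likelihood marks the tree on which the trait's evolution is more likely.
trait	logl_aapprs	logl_ssu_rdna
Stalk support	-28.22	-31.18
Polar granules	-16.97	-15.56
Aggregation	-15.10	-13.76
Habit	-19.21	-18.88
Sorocarp branching	-27.15	-29.74
Lateral branches	-25.01	-32.30
Regular whorls	-9.22	-9.69
Pointed stalk tip	-19.81	-24.16
Broadened_tip	-23.75	-27.59
Stalked_migration	-33.67	-30.27
Free_migration	-17.23	-19.81
Phototropism	-23.78	-23.03
Microcyst	-18.99	-17.65
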