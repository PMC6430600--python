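# Published ratios of averaged ancestral-state variances (AAPPRS tree over
# SSU rDNA tree) for 12 continuous Dictyostelia traits reconstructed under
# Brownian motion. Ratios below 1 mean tighter ancestral estimates on the
# AAPPRS phylogeny.
trait	variance_ratio_aapprs_over_ssu
Spore diameter	0.22
Spore eccentricity	0.21
Amoeba diameter	0.23
Amoeba eccentricity	0.13
Aggregate diameter	0.21
Sorogen length	0.54
Sorus diameter	0.26
Stalk area	0.21
Stalk eccentricity	0.39
Anterior prestalk	0.30
Posterior prespore	0.19
Rearguard region	0.15
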