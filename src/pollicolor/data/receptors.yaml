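# Default photoreceptor definitions per viewer.
#
# Sensitivity curves are generated from an A1 visual-pigment alpha-band
# nomogram parameterized by lambda_max, peak-normalized to 1.  Hawkmoth
# lambda_max values and receptor densities are measured values for a
# nocturnal sphingid; the fly lambda_max values are configurable stand-ins
# for the pale (R7p/R8p) and yellow (R7y/R8y) ommatidial receptor pairs.
hawkmoth:
  names: [UV, B, G]
  lambda_max: [357, 450, 520]
  densities: [0.1, 0.23, 0.67]
blowfly:
  names: [R7p, R8p, R7y, R8y]
  lambda_max: [330, 460, 350, 530]
  densities: [1.0, 1.0, 1.0, 1.0]
hoverfly:
  names: [R7p, R8p, R7y, R8y]
  lambda_max: [335, 455, 355, 540]
  densities: [1.0, 1.0, 1.0, 1.0]
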