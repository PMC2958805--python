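# Substrate-partition anchor points: fraction of aerobic energy expenditure
# derived from carbohydrate (plasma glucose plus muscle glycogen) at three
# relative exercise intensities.
#
# Source: digitized from Romijn et al. (1993), "Regulation of endogenous fat
# and carbohydrate metabolism in relation to exercise intensity and duration",
# Am J Physiol 265:E380-E391 (trained subjects, 25/65/85 %VO2max protocol,
# substrate oxidation after 30 min of exercise).
#
# Digitization is accurate to a few percent, not exact; values were fixed once
# and are the single empirical ingredient of the model.
#
# Columns:
#   intensity  fraction of VO2max (dimensionless)
#   f_cho      fraction of energy expenditure from carbohydrate oxidation
#   x_cho      whole-body carbohydrate oxidation rate, cal.kg-1.min-1
#   x_fat      whole-body fat oxidation rate, cal.kg-1.min-1
#   se_cho     standard error of x_cho, cal.kg-1.min-1
#   se_fat     standard error of x_fat, cal.kg-1.min-1
intensity	f_cho	x_cho	x_fat	se_cho	se_fat
0.25	0.15	12.60	71.40	0.70	2.00
0.65	0.44	95.92	122.08	5.00	5.00
0.85	0.69	196.65	88.35	6.00	6.00
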