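# Column-mapping template for a DHS child recode (KR file) exported to CSV.
#
# Adapt the source names to the survey wave at hand; variable naming is
# stable across standard DHS waves but PCV and later antigens appear
# under country-specific s-variables in older files. Notes:
#   * export the KR file to CSV first (e.g. with pyreadstat or Stata);
#     divide v005 by 1,000,000 during export to obtain the weight,
#   * dose codes: 1 = card, 2 = mother's report, 3 = card (date) -> received;
#     0 = no; 8/9 = don't know/missing -> treated as missing, later
#     counted as not received with a logged tally,
#   * precomputed DHS wealth quintiles (v190) can be mapped to
#     ses_quintile directly, bypassing the asset-battery PCA.
mapping:
  age_months: hw1                  # age of child in months (or b19)
  sex:
    source: b4
    recode: {1: male, 2: female}
  region: v024                     # region of residence (label or code)
  residence:
    source: v025
    recode: {1: urban, 2: rural}
  maternal_education:
    source: v106
    recode: {0: none, 1: primary, 2: "secondary+", 3: "secondary+"}
  insured:
    source: v481
    recode: {0: "no", 1: "yes"}
  weight: wt                       # v005 / 1e6, prepared at export time
  ses_quintile:
    source: v190
    recode: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  bcg:
    source: h2
    recode: {0: 0, 1: 1, 2: 1, 3: 1}
    default: .nan                  # 8/9 "don't know" -> missing
  opv0: {source: h0,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  opv1: {source: h4,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  opv2: {source: h6,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  opv3: {source: h8,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  dpt1: {source: h3,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  dpt2: {source: h5,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  dpt3: {source: h7,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  mcv1: {source: h9,  recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  pcv1: {source: sh1, recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  pcv2: {source: sh2, recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
  pcv3: {source: sh3, recode: {0: 0, 1: 1, 2: 1, 3: 1}, default: .nan}
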