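# Simplified IUCN Red List rule-engine thresholds.
#
# These defaults follow the standard published category bounds (criteria
# A, B2, C, D) in reduced form; they are external to any single study and
# are meant to be edited.  Categories are evaluated per criterion from the
# supplied inputs; the overall category is the highest triggered.
#
# decline_fraction: population-size reduction over the assessment window.
# range_area_km2:   area of occupancy.
# n_locations:      number of known locations.
# population_size:  mature individuals.
# local_extinction: whether local population extinctions were observed
#                   (treated as quantitative evidence of collapse).

A_decline:          # criterion A: population size reduction
  VU: 0.30
  EN: 0.50
  CR: 0.80
B2_area_km2:        # criterion B2: restricted area of occupancy
  VU: 2000
  EN: 500
  CR: 10
B2_locations:       # subcondition: few locations (applies with B2 area)
  VU: 10
  EN: 5
  CR: 1
C_population:       # criterion C: small population size and decline
  VU: 10000
  EN: 2500
  CR: 250
D_population:       # criterion D1: very small population
  VU: 1000
  EN: 250
  CR: 50
D2_locations: 5     # criterion D2: very restricted (-> VU)
E_local_extinction: CR   # observed local extinction escalates to CR
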