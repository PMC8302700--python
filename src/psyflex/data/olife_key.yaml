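# Scoring key for the 43-item short-form O-LIFE (Oxford-Liverpool Inventory
# of Feelings and Experiences), codebook item order.
#
# Facets: unusual experiences (UE, 12 items), cognitive disorganisation
# (CD, 11 items), introvertive anhedonia (IA, 10 items), impulsive
# nonconformity (IN, 10 items). Item numbers are 1-based positions in the
# codebook's item order; edit this file if your export orders items
# differently. `reverse` lists items whose schizotypy-keyed response is
# "no" — empty here because the default codebook stores already-keyed
# (endorsement = schizotypy-consistent) responses.
facets:
  UE: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
  CD: [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23]
  IA: [24, 25, 26, 27, 28, 29, 30, 31, 32, 33]
  IN: [34, 35, 36, 37, 38, 39, 40, 41, 42, 43]
reverse: []
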