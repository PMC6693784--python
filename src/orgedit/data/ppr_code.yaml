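# Combinatorial PPR code: residue at motif position 6 + residue at position 1'
# of the next motif -> ranked nucleotide preferences.
#
# Transcribed from the published statistical codes for editing-factor PLS
# arrays (Barkan et al. 2012 PLoS Genet 8:e1002910; Takenaka et al. 2013
# PLoS ONE 8:e65343; Yagi et al. 2013 PLoS ONE 8:e57286). Weights are
# approximate relative preferences normalised to sum <= 1 per pair and are
# fully user-replaceable; tests rely only on toy tables.
#
# Keys are "aa6/aa1prime" in one-letter code; U is written as T (cDNA).
code:
  T/D: {G: 0.85, A: 0.10}
  T/N: {A: 0.75, G: 0.15}
  S/N: {A: 0.80, C: 0.10}
  S/D: {G: 0.65, A: 0.15}
  S/C: {A: 0.55, C: 0.25}
  N/D: {T: 0.70, C: 0.20}
  N/N: {C: 0.50, T: 0.40}
  N/S: {C: 0.75, T: 0.15}
  N/T: {C: 0.55, T: 0.30}
  G/D: {T: 0.55, G: 0.20}
  G/N: {A: 0.50, T: 0.25}
  T/S: {A: 0.50, G: 0.25}
  A/D: {G: 0.45, T: 0.25}
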