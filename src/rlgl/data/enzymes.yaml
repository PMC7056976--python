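# Restriction enzymes bundled with rlgl (version 1).
#
# cut_top / cut_bottom are offsets from the 5' end of the recognition
# sequence on the top strand; cut_top < cut_bottom leaves a 5' overhang,
# cut_top > cut_bottom a 3' overhang, equality a blunt cut.  Values are
# the standard catalog (REBASE) positions and are cross-checked against
# Bio.Restriction by the test suite.
version: 1
enzymes:
  EcoRI: {site: GAATTC, cut_top: 1, cut_bottom: 5}
  AscI: {site: GGCGCGCC, cut_top: 2, cut_bottom: 6}
  AgeI: {site: ACCGGT, cut_top: 1, cut_bottom: 5}
  StuI: {site: AGGCCT, cut_top: 3, cut_bottom: 3}
  BamHI: {site: GGATCC, cut_top: 1, cut_bottom: 5}
  BglII: {site: AGATCT, cut_top: 1, cut_bottom: 5}
  XhoI: {site: CTCGAG, cut_top: 1, cut_bottom: 5}
  SbfI: {site: CCTGCAGG, cut_top: 6, cut_bottom: 2}
  SacII: {site: CCGCGG, cut_top: 4, cut_bottom: 2}
  NheI: {site: GCTAGC, cut_top: 1, cut_bottom: 5}
  SpeI: {site: ACTAGT, cut_top: 1, cut_bottom: 5}
  FseI: {site: GGCCGGCC, cut_top: 6, cut_bottom: 2}
  NotI: {site: GCGGCCGC, cut_top: 2, cut_bottom: 6}
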