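# Reference identification matrix: 28 commercial tattoo inks and 18
# equal-weight lab pigment mixtures analysed by pyrolysis GC/MS with both
# evaluation approaches.  declared: ';'-joined pigment ids, '?' = no label
# information; ams: single best AMS hit ('|' joins ambiguity-group members,
# '-' = no hit); fragment: ';'-joined fragment-comparison hits, each an
# ambiguity group ('-' = none).
sample,kind,declared,ams,fragment
ink-01,ink,?,-,P.B.15
ink-02,ink,P.B.15,P.B.15,P.B.15
ink-03,ink,P.B.15,P.B.15,P.B.15
ink-04,ink,P.B.15,P.B.15,P.B.15
ink-05,ink,P.B.15;P.R.170,P.R.170|P.R.210,P.R.170|P.R.210
ink-06,ink,P.B.15;P.R.202;P.V.37,P.V.37,P.B.15
ink-07,ink,P.G.36,P.G.36,P.G.36
ink-08,ink,P.G.36;P.Y.154,P.Y.154,P.G.36;P.Y.154
ink-09,ink,P.O.13;P.Y.65,P.Y.74|P.Y.65,P.Y.74|P.Y.65
ink-10,ink,P.O.13;P.R.210,P.R.170|P.R.210,P.R.146;P.R.170|P.R.210
ink-11,ink,P.O.16;P.Y.14,P.O.16,P.Y.1;P.O.16
ink-12,ink,P.O.73;P.Y.138,P.O.73,P.O.73;P.Y.138
ink-13,ink,P.O.73;P.Y.138,P.Y.138,P.O.73;P.Y.138
ink-14,ink,P.O.73;P.Y.97;P.R.202,P.Y.97,P.Y.97
ink-15,ink,P.R.170,P.R.170|P.R.210,P.R.170|P.R.210
ink-16,ink,P.R.170,P.R.170|P.R.210,P.R.170|P.R.210
ink-17,ink,P.R.177,P.R.177,P.R.177
ink-18,ink,P.R.254,P.R.254,P.R.254
ink-19,ink,P.R.254,P.R.254,P.R.254
ink-20,ink,P.R.254,P.R.254,P.R.254
ink-21,ink,P.R.254;P.R.177,P.R.254,P.R.177;P.R.254
ink-22,ink,P.Y.14,P.Y.14,P.Y.74;P.Y.14
ink-23,ink,P.Y.14,P.Y.14,P.Y.14
ink-24,ink,P.Y.65,P.Y.74|P.Y.65,P.Y.74|P.Y.65
ink-25,ink,P.Y.138,P.B.15,P.Y.138
ink-26,ink,P.Y.138,P.Y.138,P.Y.138
ink-27,ink,P.Y.138,P.Y.138,P.Y.138
ink-28,ink,P.Y.154,P.Y.154,P.Y.154
mix-01,mix,P.B.15;P.V.23,P.R.254,P.B.15;P.V.23
mix-02,mix,P.O.43;P.R.112,P.R.112,P.R.112
mix-03,mix,P.O.73;P.R.254,P.R.254,P.O.73;P.R.254
mix-04,mix,P.O.5;P.Y.83,P.Y.83,P.O.5;P.Y.83
mix-05,mix,P.O.16;P.Y.14,P.Y.14,P.O.16;P.Y.14
mix-06,mix,P.R.112;P.R.202;P.R.254,P.Y.138,P.R.112;P.R.254
mix-07,mix,P.R.4;P.Y.3,P.R.4,P.R.4;P.Y.3
mix-08,mix,P.R.5;P.Y.83,P.Y.83,P.R.5;P.Y.83
mix-09,mix,P.R.5;P.Y.97,P.Y.97,P.R.5;P.Y.97
mix-10,mix,P.R.5;P.Y.1,P.R.5,P.R.5;P.Y.1
mix-11,mix,P.R.22;P.Y.1,P.Y.1,P.R.22;P.Y.1
mix-12,mix,P.R.22;P.Y.74,P.Y.74|P.Y.65,P.R.22;P.Y.74|P.Y.65
mix-13,mix,P.R.122;P.Y.1,P.Y.1,P.Y.1
mix-14,mix,P.R.122;P.R.202;P.V.19,P.R.177,-
mix-15,mix,P.R.254;P.Y.3,P.Y.3,P.R.254;P.Y.3
mix-16,mix,P.R.254;P.Y.74,P.Y.74|P.Y.65,P.R.254;P.Y.74|P.Y.65
mix-17,mix,P.V.19,P.R.177,-
mix-18,mix,P.Y.14;P.V.23,P.Y.14,P.Y.14;P.V.23
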