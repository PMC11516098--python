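# Pharmacophore feature typing for the built-in conformer-pair scorer.
# Each entry maps a feature type to a list of SMARTS patterns; a feature of
# that type is present wherever any pattern matches. Edit or point the
# scorer at another file to change the typing rules.
donor:
  - "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),$([n&H1&+0])]"
acceptor:
  - "[$([O;H0;v2]),$([O;-]),$([N;v3;!$(N-*=[O,N,P,S])]),$([n&H0&+0]),$([o;+0;!$([o]:n);!$([o]:c:n)])]"
aromatic:
  - "a1aaaaa1"
  - "a1aaaa1"
hydrophobe:
  - "[C&D3,C&D4;!$(C=[O,N,S]);!$(C#N)]"
  - "[CH3]"
  - "[S;D2;$(S(C)(C))]"
  - "[Cl,Br,I]"
cation:
  - "[+,+2,+3;!$([N+]-[O-])]"
  - "[$([N;H2&+0][C;!$(C=*)]);!$(N[a])]"
anion:
  - "[-,-2,-3;!$([O-]-[N+])]"
  - "[$([C,S](=[O,S,P])-[O;H1])]"
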