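# Curated species groups whose members are documented to be closely
# related: a single-linkage cluster containing >2 reference sequences is
# given the group name when its reference species all belong to one of
# these sets. Edit freely to add local curation.
L. plantarum spp. group:
  - L. plantarum
  - L. pentosus
  - L. fabifermentans
L. casei spp. group:
  - L. casei
  - L. paracasei
  - L. zeae
  - L. rhamnosus
L. crustorum spp. group:
  - L. crustorum
  - L. mindensis
  - L. farcisminis
A. lovaniensis spp. group:
  - A. lambici
  - A. lovaniensis
  - A. okinawensis
  - A. syzygii
  - A. ghanensis
  - A. fabarum
A. malorum spp. group:
  - A. orientalis
  - A. farinalis
  - A. malorum
  - A. cerevisiae
  - A. persici
  - A. cibinongensis
G. frateurii spp. group:
  - G. wanchernii
  - G. jabonicus
  - G. thailandicus
  - G. cerinus
  - G. nephelii
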