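# Glires clade partition: 35 taxa (30 Glires, Tupaia chinensis, 4 outgroups).
# Levels map clade label -> taxa. Composite clades (reported as single
# specificity labels in the CSI catalog) live on their own levels because a
# taxon carries exactly one label per level.
# Tupaia_chinensis (Scandentia) is deliberately not an outgroup: the composite
# candidate clade "Glires and Scandentia" may not intersect the outgroup set.
name: glires

outgroups:
  - Homo_sapiens
  - Pan_troglodytes
  - Macaca_mulatta
  - Galeopterus_variegatus

levels:
  grandorder:
    Glires: &glires
      - Oryctolagus_cuniculus
      - Ochotona_princeps
      - Lepus_europaeus
      - Ictidomys_tridecemlineatus
      - Marmota_marmota
      - Sciurus_carolinensis
      - Urocitellus_parryii
      - Cavia_porcellus
      - Chinchilla_lanigera
      - Octodon_degus
      - Heterocephalus_glaber
      - Fukomys_damarensis
      - Castor_canadensis
      - Dipodomys_ordii
      - Dipodomys_spectabilis
      - Jaculus_jaculus
      - Zapus_hudsonius
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
    Euarchonta:
      - Tupaia_chinensis
      - Homo_sapiens
      - Pan_troglodytes
      - Macaca_mulatta
      - Galeopterus_variegatus
  order:
    Rodentia: &rodentia
      - Ictidomys_tridecemlineatus
      - Marmota_marmota
      - Sciurus_carolinensis
      - Urocitellus_parryii
      - Cavia_porcellus
      - Chinchilla_lanigera
      - Octodon_degus
      - Heterocephalus_glaber
      - Fukomys_damarensis
      - Castor_canadensis
      - Dipodomys_ordii
      - Dipodomys_spectabilis
      - Jaculus_jaculus
      - Zapus_hudsonius
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
    Lagomorpha: &lagomorpha
      - Oryctolagus_cuniculus
      - Ochotona_princeps
      - Lepus_europaeus
    Primates:
      - Homo_sapiens
      - Pan_troglodytes
      - Macaca_mulatta
    Scandentia:
      - Tupaia_chinensis
    Dermoptera:
      - Galeopterus_variegatus
  suborder:
    Sciuromorpha: &sciuromorpha
      - Ictidomys_tridecemlineatus
      - Marmota_marmota
      - Sciurus_carolinensis
      - Urocitellus_parryii
    Hystricomorpha: &hystricomorpha
      - Cavia_porcellus
      - Chinchilla_lanigera
      - Octodon_degus
      - Heterocephalus_glaber
      - Fukomys_damarensis
    Castorimorpha: &castorimorpha
      - Castor_canadensis
      - Dipodomys_ordii
      - Dipodomys_spectabilis
    Myomorpha: &myomorpha
      - Jaculus_jaculus
      - Zapus_hudsonius
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
  family:
    Dipodoidea:
      - Jaculus_jaculus
      - Zapus_hudsonius
    Spalacidae:
      - Nannospalax_galili
    Muridae: &muridae
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
    Cricetidae: &cricetidae
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
  superfamily:
    Muroidea:
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
  glires_scandentia:
    Glires and Scandentia:
      - Tupaia_chinensis
      - Oryctolagus_cuniculus
      - Ochotona_princeps
      - Lepus_europaeus
      - Ictidomys_tridecemlineatus
      - Marmota_marmota
      - Sciurus_carolinensis
      - Urocitellus_parryii
      - Cavia_porcellus
      - Chinchilla_lanigera
      - Octodon_degus
      - Heterocephalus_glaber
      - Fukomys_damarensis
      - Castor_canadensis
      - Dipodomys_ordii
      - Dipodomys_spectabilis
      - Jaculus_jaculus
      - Zapus_hudsonius
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
  myomorpha_castorimorpha:
    Myomorpha and Castorimorpha:
      - Castor_canadensis
      - Dipodomys_ordii
      - Dipodomys_spectabilis
      - Jaculus_jaculus
      - Zapus_hudsonius
      - Nannospalax_galili
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus
  muridae_cricetidae:
    Muridae and Cricetidae:
      - Mus_musculus
      - Rattus_norvegicus
      - Rattus_rattus
      - Mastomys_coucha
      - Grammomys_surdaster
      - Arvicanthis_niloticus
      - Peromyscus_maniculatus
      - Microtus_ochrogaster
      - Mesocricetus_auratus
      - Cricetulus_griseus
      - Onychomys_torridus
      - Ondatra_zibethicus

candidate_clades:
  - {level: grandorder, label: Glires}
  - {level: order, label: Rodentia}
  - {level: order, label: Lagomorpha}
  - {level: suborder, label: Sciuromorpha}
  - {level: suborder, label: Hystricomorpha}
  - {level: suborder, label: Castorimorpha}
  - {level: suborder, label: Myomorpha}
  - {level: family, label: Muridae}
  - {level: family, label: Cricetidae}
  - {level: superfamily, label: Muroidea}
  - {level: glires_scandentia, label: Glires and Scandentia}
  - {level: myomorpha_castorimorpha, label: Myomorpha and Castorimorpha}
  - {level: muridae_cricetidae, label: Muridae and Cricetidae}
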