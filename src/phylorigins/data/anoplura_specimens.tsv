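species	taxon_label	endosymbiont_present	at_percents
Proechinophthirus fluctus	Echin3.17.09.2	yes	45
Haematopinus suis	Hpsu7.14.09.4	yes	52
Ancistroplax crocidurae 1	Axcro4.26.09.1	yes	50
Ancistroplax crocidurae 2	Axsp7.14.09.5	yes	49,45
Hoplopleura ferrisi 2	Hofer7.14.09.8	no
Hoplopleura hirsuta	Hosp4.17.09.7	no
Hoplopleura onychomydis	Hoony8.27.08.6	no
Hoplopleura reithrodontomydis 2	Hosp7.14.09.6	no
Hoplopleura sicata	Hosic7.14.09.9	no
Linognathus spicatus	Linog6.22.09.1	yes	52
Pedicinus pictus 1	Qnpic3.31.08.1	yes	54
Pedicinus pictus 2	Qnpic6.30.09.2	yes	53
Pedicinus pictus 3	Qnsp3.31.08.3	yes	54
Pediculus humanus capitis	Pdcap9.20.05.2NW	yes	51
Pediculus humanus humanus	Pdhum5.19.05.2	yes	51
Fahrenholzia ehrlichi 1	Fzehr8.20.08.1	yes	52
Fahrenholzia ehrlichi 2	Fzehr6.30.09.4	yes	51
Linognathoides marmotae 1	Lnlae6.30.09.3	yes	54
Lemurpediculus verruculosus 1	Lesp4.26.09.2	yes	53
Neohaematopinus sciuropteri	Nescp6.30.09.5	yes	53
Neohaematopinus neotomae	Neneo8.20.08.2	no
Sathrax durus	Sathrax4.26.09.3	yes	45
Pthirus gorillae	Ptgor9.14.08.1	yes	53
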