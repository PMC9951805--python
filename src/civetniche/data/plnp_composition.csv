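item,group,fo_asian_palm_civet,fo_small_indian_civet
Indian gerbil (Tatera indica),wild animal,19,7
Rhesus monkey (Macaca mulatta),wild animal,8,0
Norway rat (Rattus norvegicus),wild animal,7,2
House mouse (Mus musculus),wild animal,6,3
Roof or house rat (Rattus rattus),wild animal,4,1
Desert hare (Lepus nigricollis dayanus),wild animal,5,0
Himalayan bulbul (Pycnonotus leucogenys),wild animal,0,2
House sparrow (Passer domesticus),wild animal,0,1
Amphibians,wild animal,0,2
Snail (Cornu spp.),wild animal,7,0
Insects (Orthoptera) grasshopper,wild animal,7,1
Insects (Coleoptera) beetle,wild animal,2,0
Chicken (Gallus gallus domesticus),domestic animal,13,9
Cattle (Bos taurus),domestic animal,7,0
Sheep (Ovis aries),domestic animal,1,0
Wild Himalayan pear (Pyrus pashia),plant,53,15
Blackberry (Rubus fruticosus),plant,11,5
Jujube (Ziziphus oxyphylla),plant,10,2
Olea (Olea ferruginea),plant,6,2
Jujube (Ziziphus jujube),plant,4,0
Date-plum (Diospyros lotus),plant,4,1
Loquat (Eriobotrya japonica),plant,0,3
Loonder grass (Themeda anathera),plant,2,0
Apple (Pyrus malus),plant,2,3
Apricot (Prunus armeniaca),plant,2,0
Wild fig (Ficus carica),plant,2,0
Watermelon (Citrullus lanatus),plant,2,1
Coriander (Coriandrum sativum),plant,2,0
Indian ash tree (Lannea coromandelica),plant,1,0
Orange (Citrus reticulate),plant,1,0
Wheat (Triticum aestivum),plant,1,0
Grit,other,3,1
Artificial matter,other,1,1
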