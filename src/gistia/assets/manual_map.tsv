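archetecture	architecture
backround	background
beutiful	beautiful
bulding	building
buliding	building
childrens	child
foilage	foliage
grafitti	graffiti
mountian	mountain
moutain	mountain
outdors	outdoor
peaple	person
relfection	reflection
restraunt	restaurant
scenary	scenery
silouette	silhouette
skyscrapper	skyscraper
wether	weather
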