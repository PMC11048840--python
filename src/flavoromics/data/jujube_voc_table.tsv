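compound	category	threshold_ug_per_kg	odor_type	HZ	HMZ	QYX	roav_HZ	roav_HMZ	roav_QYX
Heptanoic acid	acid	3000	Rancid, sour, cheesy, and sweat	0.006	0.012	0.013	0.000	0.000	0.000
Tetradecanoic acid	acid	10000	Faint waxy, fatty, pineapple, and citrus peel	47.668	37.179	42.414	0.047	0.062	0.039
Dodecanoic acid	acid	10000	Mild fatty and coconut bay oil	3.511	1.097	2.078	0.003	0.002	0.002
n-Hexadecanoic acid	acid	2000	Slightly waxy and fatty	7.755	9.221	16.532	0.038	0.077	0.076
Octanoic acid	acid	910	Fatty, waxy, rancid, vegetable, and cheesy	0.219	0.204	0.179	0.002	0.004	0.002
Butanoic acid	acid	1400	Dairy-like, cheesy, buttery, and fruity	0.094	0.134	0.079	0.001	0.002	0.001
n-Decanoic acid	acid	10000	Unpleasant, rancid, and sour	0.002	0.076	0.060	0.000	0.000	0.000
Pentanoic acid	acid	280	Sour milky, tobacco, and fruity	0.026	0.168	0.014	0.001	0.010	0.000
1-Octen-3-ol	alcohol	1	Mushroom, vegetative, earthy, and oily	0.092	0.141	0.043	0.902	2.361	0.392
(E)-2-Nonenal	aldehyde	0.08	Fatty, green, citrus, cucumber, and melon	0.458	0.479	0.158	56.318	100.00	18.175
(E)-2-Decenal	aldehyde	0.3	Fatty, earthy, green, cilantro, and fat tallow	3.049	0.919	3.252	100.00	51.163	100.00
Hexanal	aldehyde	4.5	Fresh, green, fatty, and fruity (apple, citrus, and orange)	0.013	0.052	0.083	0.028	0.192	0.170
Nonanal	aldehyde	1	Fruity, floral, and fatty (rose, orange, melon, nutty, and coconut)	0.661	1.009	0.126	6.499	16.840	1.161
Benzaldehyde	aldehyde	320	Strong sharp bitter almond and woody	0.089	0.108	0.032	0.003	0.006	0.001
(Z)-2-Heptenal	aldehyde	13	Apple and vegetable	0.017	0.051	0.007	0.013	0.066	0.005
Heptanal	aldehyde	3	Fresh, fatty, and green herbal	0.879	1.242	1.292	2.882	6.913	3.973
(E)-2-Hexenal	aldehyde	17	Green, banana, cheesy, and vegetative	0.027	0.098	0.147	0.016	0.096	0.080
Decanal	aldehyde	0.1	Sweet, orange peel, citrus floral, and green melon	0.017	0.026	0.011	1.712	4.291	1.042
Benzeneacetaldehyde	aldehyde	4	Honey, sweet, floral, chocolate, and spicy	0.088	0.146	0.060	0.216	0.609	0.139
(E)-2-Octenal	aldehyde	3	Fresh, green, fatty, cucumber, herbal, and banana	0.000	0.014	0.005	0.001	0.080	0.014
Octanal	aldehyde	0.7	Citrus peel, green herbal, fresh, and fatty	0.377	1.053	0.230	5.305	25.111	3.030
Furfural	aldehyde	282	Sweet, nutty, caramellic, almond, and baked bread	0.009	0.097	0.020	0.000	0.006	0.001
Hexadecanoic acid ethyl ester	ester	2000	Mild fruity, creamy, balsamic, and greasy	0.167	1.427	0.744	0.001	0.012	0.003
3-Octanone	ketone	28	Fresh, sweet, herbal, lavender, and mushroom	0.158	0.162	0.672	0.056	0.097	0.222
5-ethyldihydro-2(3H)-Furanone	ester	1600	Sweet, creamy, tobacco, and green coconut	0.423	0.557	1.353	0.003	0.006	0.008
6-methyl-5-Hepten-2-one	ketone	100	Fruity, apple, musty, creamy, slight cheesy, and banana	0.254	0.084	0.173	0.025	0.014	0.016
2-pentyl-Furan	other	6	Fruity, green, bean, and vegetable	0.052	0.109	0.036	0.086	0.303	0.056
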