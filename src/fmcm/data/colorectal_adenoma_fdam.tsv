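# Published function-drug association screen for colorectal adenoma.
# Modules: At apoptosis, CC cell cycle, CP cell proliferation, DR DNA replication,
# IS immune system process, RM RNA metabolic process, Ts transcription, ST signal transduction.
# Negative ES = beneficial link (signature reversal), positive ES = harmful link.
drug	module	es
phenoxybenzamine	CC	-0.987
phenoxybenzamine	DR	-0.983
phenoxybenzamine	At	-0.977
phenoxybenzamine	CP	-0.962
phenoxybenzamine	Ts	-0.905
phenoxybenzamine	ST	-0.886
phenoxybenzamine	RM	-0.81
GW-8510	CP	-0.972
GW-8510	ST	-0.936
GW-8510	DR	-0.882
GW-8510	At	-0.867
GW-8510	CC	-0.834
GW-8510	Ts	-0.822
GW-8510	RM	-0.791
thapsigargin	At	-0.918
thapsigargin	ST	0.4
thapsigargin	Ts	0.521
thapsigargin	CP	0.528
thapsigargin	RM	0.887
phthalylsulfathiazole	Ts	-0.882
phthalylsulfathiazole	RM	-0.874
phthalylsulfathiazole	CP	-0.767
phthalylsulfathiazole	IS	-0.771
phthalylsulfathiazole	DR	-0.705
medrysone	DR	-0.755
medrysone	Ts	-0.698
medrysone	CP	-0.675
medrysone	IS	-0.686
medrysone	ST	-0.658
0297417-0002B	DR	-0.981
0297417-0002B	RM	-0.966
0297417-0002B	Ts	-0.943
0297417-0002B	IS	0.668
daunorubicin	CC	-0.867
daunorubicin	CP	-0.844
daunorubicin	RM	-0.8
daunorubicin	ST	-0.786
0175029-0000	Ts	-0.771
0175029-0000	CP	-0.766
0175029-0000	ST	-0.698
0175029-0000	RM	-0.69
apigenin	DR	-0.896
apigenin	CP	-0.837
apigenin	Ts	-0.796
apigenin	RM	-0.784
pyrvinium	CC	-0.75
pyrvinium	At	-0.694
pyrvinium	IS	0.314
trifluoperazine	CC	-0.604
trifluoperazine	DR	-0.501
trifluoperazine	IS	0.415
camptothecin	At	-0.953
camptothecin	CP	-0.935
camptothecin	ST	-0.878
meticrane	Ts	-0.726
meticrane	At	-0.72
meticrane	RM	-0.713
ellipticine	At	-0.827
ellipticine	IS	0.422
8-azaguanine	At	-0.87
8-azaguanine	CP	-0.83
etacrynic acid	At	-0.891
etacrynic acid	CC	-0.875
alsterpaullone	ST	-0.874
alsterpaullone	At	-0.866
vorinostat	CP	-0.592
vorinostat	ST	-0.503
thioguanosine	DR	-0.935
thioguanosine	Ts	-0.811
sulconazole	DR	-0.869
sulconazole	Ts	-0.814
chrysin	Ts	-0.934
chrysin	DR	-0.913
thiostrepton	DR	-0.837
thiostrepton	Ts	-0.816
luteolin	Ts	-0.856
luteolin	DR	-0.811
ifenprodil	RM	-0.839
ifenprodil	Ts	-0.779
doxazosin	At	-0.804
cycloserine	At	-0.799
repaglinide	At	-0.795
flufenamic acid	At	-0.665
irinotecan	At	-0.871
resveratrol	CC	-0.627
withaferin A	CC	-0.799
clioquinol	CC	-0.719
doxorubicin	CC	-0.874
bepridil	CP	-0.791
cloperastine	DR	-0.683
piperlongumine	DR	-0.956
morantel	IS	-0.839
cetirizine	IS	-0.845
ginkgolide A	IS	-0.834
cefalexin	IS	-0.744
triflusal	IS	-0.891
imipenem	IS	-0.791
skimmianine	RM	-0.815
6-azathymine	ST	-0.813
tyloxapol	ST	-0.783
sanguinarine	Ts	-0.959
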