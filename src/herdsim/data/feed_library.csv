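# Packaged fixture feed library (synthetic reconstruction).
# Composition per kg DM, NRC (2001) feed-table style values for the five
# ration feeds of the case-study herd plus the two calf feeds.  Values are
# documented reconstructions typical of the named feeds, not transcriptions.
# Columns: price $/kg DM; dm as-fed fraction; nel Mcal/kg DM; mp g/kg DM;
# cp,ndf,fat,ca,p,starch % of DM; forage 1/0; max_inclusion kg DM/d (-1 = none).
name,price,dm,nel,mp,cp,ndf,forage,fat,ca,p,starch,max_inclusion
corn_silage,0.07,0.35,1.45,45,8.8,45.0,1,3.2,0.28,0.26,35.0,-1
soybean_meal,0.35,0.90,2.13,300,53.8,9.8,0,1.6,0.40,0.71,2.7,10
brewers_grain_wet,0.10,0.24,1.56,150,28.4,47.1,0,5.2,0.30,0.67,5.0,4
dicalcium_phosphate,0.60,0.97,0.0,0,0.0,0.0,0,0.0,22.0,18.5,0.0,0.3
limestone,0.10,0.98,0.0,0,0.0,0.0,0,0.0,34.0,0.0,0.0,0.3
milk_replacer,2.20,0.95,2.40,220,24.0,0.0,0,18.0,1.0,0.7,0.0,-1
calf_starter,0.40,0.90,1.90,130,20.0,18.0,0,3.5,0.7,0.45,35.0,-1
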