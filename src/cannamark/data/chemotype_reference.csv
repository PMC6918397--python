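variety,n_plants,CBD,SD_CBD,THC,SD_THC,printed_ratio,class
Santhica 27,5,0.00,,0.00,,0.0,fiber
Carmagnola,5,3.89,0.49,0.24,0.04,0.06,fiber
Uso 31,5,0.24,0.13,0.03,0.02,0.12,fiber
Ermes,5,2.53,0.37,0.15,0.03,0.06,fiber
Finola,5,1.66,0.34,0.31,0.1,0.18,fiber
Ermo,5,0.01,0.01,0.00,,0.0,fiber
Futura 75,5,3.18,0.21,0.18,0.02,0.05,fiber
C.S.,5,3.91,0.36,0.24,0.02,0.08,fiber
Tygra,5,1.97,0.38,0.31,0.12,0.18,fiber
Carmaleonte,5,2.68,0.47,0.15,0.03,0.05,fiber
60 Days Wonder,3,0.22,0.19,6.97,3.64,32.17,drug
BC God Bud,11,0.20,0.08,6.40,3.89,32.00,drug
Chocolate Kush,4,0.96,0.77,5.42,2.75,5.67,drug
Chocolope,3,0.44,0.02,5.65,1.06,12.84,drug
Flash Babylon,2,0.14,0.18,7.20,0.30,51.43,drug
Golden Berry,2,0.42,0.35,11.80,4.30,28.10,drug
Northern Light,4,1.81,1.84,6.40,4.90,3.53,drug
Shiatsu Kush,8,0.40,0.19,6.10,3.39,15.44,drug
Skunk #11,4,2.15,1.34,2.08,0.77,0.97,drug
Star Ryder,4,0.84,1.04,11.33,3.28,13.53,drug
UK Werkle,2,1.54,1.79,6.70,4.70,4.36,drug
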